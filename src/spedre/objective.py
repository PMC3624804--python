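"""The collocation ("dual") objective: per-timeslice error terms and their product.

Each error term epsilon_(e,i,j) measures how badly a candidate parameter vector
violates species i's ODE at timepoint j of experiment e, with the left-hand
side interpolated from the data rather than simulated:

    epsilon = ( f_i(xhat(t_j), k) - dxhat_i/dt(t_j) )^2

where f_i is the mass-action right-hand side evaluated at the OBSERVED
(spline-smoothed, if smoothing was applied) concentrations.  Only the
parameters appearing in species i's ODE influence the term — the locality that
makes the objective decomposable.  The full objective is the product of all
error terms (POF); because the raw product under/overflows and collapses to
zero if any single term does, the normalized mean-log form is used as the
practical diagnostic.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterator, NamedTuple

import numpy as np
import pandas as pd

from .network import ReactionNetwork, ode_rhs
from .splines import DerivativeTable, TimeSeriesDataset

__all__ = [
    "ErrorTermIndex",
    "error_term",
    "error_terms",
    "iter_error_indices",
    "pof",
    "normalized_log_pof",
    "dump_error_terms",
]


class ErrorTermIndex(NamedTuple):
    """Identifies one collocation error term."""

    experiment: int
    species: int
    timepoint: int


def iter_error_indices(dataset: TimeSeriesDataset) -> Iterator[ErrorTermIndex]:
    """All (experiment, species, timepoint) triples, lexicographic order."""
    for e in range(dataset.n_experiments):
        for i in range(dataset.n_species):
            for j in range(dataset.timepoints[e].size):
                yield ErrorTermIndex(e, i, j)


def error_term(
    network: ReactionNetwork,
    params: np.ndarray,
    dataset: TimeSeriesDataset,
    derivs: DerivativeTable,
    idx: ErrorTermIndex,
    *,
    form: str = "squared",
) -> float:
    """One epsilon_(e,i,j): squared (default) or absolute ODE-violation residual."""
    e, i, j = idx
    try:
        conc = derivs.concentrations[e][j]
        lhs = derivs.derivatives[e][j, i]
    except IndexError as err:
        raise KeyError(f"no derivative entry for {idx}") from err
    rhs = ode_rhs(network, np.asarray(params, dtype=float), conc)[i]
    resid = rhs - lhs
    if form == "squared":
        return float(resid * resid)
    if form == "abs":
        return float(abs(resid))
    raise ValueError(f"unknown error-term form {form!r}")


def error_terms(
    network: ReactionNetwork,
    params: np.ndarray,
    dataset: TimeSeriesDataset,
    derivs: DerivativeTable,
    *,
    form: str = "squared",
) -> np.ndarray:
    """All error terms, flattened in lexicographic (e, i, j) order."""
    params = np.asarray(params, dtype=float)
    out = []
    for e in range(dataset.n_experiments):
        conc = derivs.concentrations[e]
        resid = np.empty_like(conc)
        for j in range(conc.shape[0]):
            resid[j] = ode_rhs(network, params, conc[j]) - derivs.derivatives[e][j]
        eps = resid**2 if form == "squared" else np.abs(resid)
        # lexicographic (i, j): species-major
        out.append(eps.T.ravel())
    return np.concatenate(out)


def pof(
    network: ReactionNetwork,
    params: np.ndarray,
    dataset: TimeSeriesDataset,
    derivs: DerivativeTable,
    *,
    form: str = "squared",
) -> float:
    """Raw product of all error terms.

    Documented hazard: returns exactly 0 if any single term is 0, and can
    under/overflow for realistic problem sizes — use
    :func:`normalized_log_pof` for comparisons.
    """
    eps = error_terms(network, params, dataset, derivs, form=form)
    return float(np.prod(eps))


def normalized_log_pof(
    network: ReactionNetwork,
    params: np.ndarray,
    dataset: TimeSeriesDataset,
    derivs: DerivativeTable,
    *,
    floor: float = 1e-12,
    form: str = "squared",
) -> float:
    """Mean natural log of the (floored) error terms; lower is better."""
    if floor <= 0:
        raise ValueError("floor must be positive")
    eps = error_terms(network, params, dataset, derivs, form=form)
    return float(np.mean(np.log(np.maximum(eps, floor))))


def dump_error_terms(
    network: ReactionNetwork,
    params: np.ndarray,
    dataset: TimeSeriesDataset,
    derivs: DerivativeTable,
    path: str | Path,
    *,
    form: str = "squared",
) -> None:
    """Diagnostic CSV of every error term keyed by (experiment, species, time)."""
    rows = []
    for idx in iter_error_indices(dataset):
        rows.append(
            {
                "experiment": dataset.experiments[idx.experiment],
                "species": dataset.species_names[idx.species],
                "time": dataset.timepoints[idx.experiment][idx.timepoint],
                "epsilon": error_term(network, params, dataset, derivs, idx, form=form),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)
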