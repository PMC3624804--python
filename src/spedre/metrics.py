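"""Estimation-quality scores: weighted SSE, species MRE, and parameter PPE.

Species MRE (maximum relative error) is the worst simulated-vs-observed
deviation over all experiments, species and timepoints, normalized per
(experiment, species) by the observed maximum of that species' time course —
values above 100% mean a trajectory missed by more than its own dynamic range
and are meaningful failure indicators.  PPE (parameter percentage error) is
100·|k_est − k_nominal|/k_nominal, aggregated by the median; it requires the
nominal parameters and so applies only to simulated tests.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .network import ReactionNetwork, simulate
from .refine import weighted_sse
from .splines import TimeSeriesDataset

__all__ = ["ScoreReport", "species_mre", "parameter_percentage_error", "score"]


@dataclass
class ScoreReport:
    """Bundle of the three quality metrics for one estimate."""

    weighted_sse: float
    species_mre_pct: float
    ppe_pct: np.ndarray | None = None

    @property
    def median_ppe_pct(self) -> float | None:
        return None if self.ppe_pct is None else float(np.median(self.ppe_pct))

    def to_dict(self) -> dict:
        return {
            "weighted_sse": self.weighted_sse,
            "species_mre_pct": self.species_mre_pct,
            "ppe_pct": None if self.ppe_pct is None else [float(v) for v in self.ppe_pct],
            "median_ppe_pct": self.median_ppe_pct,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def tsv_row(self, label: str = "") -> str:
        med = "" if self.median_ppe_pct is None else f"{self.median_ppe_pct:.6g}"
        return f"{label}\t{self.weighted_sse:.6g}\t{self.species_mre_pct:.6g}\t{med}"


def species_mre(
    network: ReactionNetwork,
    params: np.ndarray,
    dataset: TimeSeriesDataset,
    *,
    pointwise: bool = False,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> float:
    """Species maximum relative error, as a percentage.

    Default normalization is the per-(experiment, species) observed maximum
    (range normalization); ``pointwise=True`` divides by each observed value
    instead, which explodes near zero and is provided for comparison only.
    Species observed as identically zero are skipped with a warning.
    """
    params = np.asarray(params, dtype=float)
    worst = 0.0
    for e in range(dataset.n_experiments):
        obs = dataset.observations[e]
        traj = simulate(network, params, obs[0], dataset.timepoints[e], rtol=rtol, atol=atol)
        err = np.abs(traj.values - obs)
        if pointwise:
            with np.errstate(divide="ignore", invalid="ignore"):
                rel = np.where(obs > 0, err / obs, 0.0)
        else:
            peaks = obs.max(axis=0)
            zero = peaks == 0
            if np.any(zero):
                names = [dataset.species_names[i] for i in np.nonzero(zero)[0]]
                warnings.warn(f"species with all-zero observations skipped in MRE: {names}")
            rel = np.zeros_like(err)
            rel[:, ~zero] = err[:, ~zero] / peaks[~zero]
        worst = max(worst, float(rel.max()))
    return 100.0 * worst


def parameter_percentage_error(
    estimated: np.ndarray, nominal: np.ndarray
) -> tuple[np.ndarray, float]:
    """Per-parameter PPE = 100·|k_est − k|/k and its median."""
    est = np.asarray(estimated, dtype=float)
    nom = np.asarray(nominal, dtype=float)
    if est.shape != nom.shape:
        raise ValueError("estimated and nominal vectors differ in length")
    if np.any(nom <= 0):
        raise ValueError("nominal parameters must be strictly positive for PPE")
    ppe = 100.0 * np.abs(est - nom) / nom
    return ppe, float(np.median(ppe))


def score(
    network: ReactionNetwork,
    params: np.ndarray,
    dataset: TimeSeriesDataset,
    nominal: np.ndarray | None = None,
    weights: np.ndarray | None = None,
) -> ScoreReport:
    """All three metrics in one report (PPE only when nominal truth is given)."""
    ppe = None if nominal is None else parameter_percentage_error(params, nominal)[0]
    return ScoreReport(
        weighted_sse=weighted_sse(network, params, dataset, weights),
        species_mre_pct=species_mre(network, params, dataset),
        ppe_pct=ppe,
    )
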