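"""Discretized factor-graph inference over rate parameters (the base estimator).

The collocation objective factorizes over (experiment, species, timepoint)
error terms, each involving only the few parameters appearing in that species'
ODE.  Discretizing every parameter into equidistant bins (each represented by
its midpoint) turns each error term into a small d-dimensional look-up table of
Boltzmann-weighted probabilities, p ∝ exp(-beta * epsilon), computed once for
every bin combination and never mutated afterwards.  Max-product loopy belief
propagation on the resulting bipartite graph then yields an approximate MAP
bin assignment per parameter.

The message-passing variant implemented here sends each variable's CURRENT
FULL BELIEF to factors (rather than the textbook product-of-other-messages);
the textbook exclusion rule is available behind ``standard_bp=True``.  All
message arithmetic is carried out in log space, with max-subtraction before
exponentiation, so that tiny probabilities are never rounded to zero; messages
and beliefs are renormalized to valid probability distributions after every
update.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .network import ReactionNetwork, params_in_ode
from .objective import ErrorTermIndex
from .splines import DerivativeTable, TimeSeriesDataset, interpolated_derivatives

__all__ = [
    "ParameterBins",
    "DiscretizationScheme",
    "JointTable",
    "FactorNode",
    "FactorGraph",
    "MAPResult",
    "build_bins",
    "build_factor_graph",
    "compute_joint_table",
    "table_argmax",
    "max_marginalize",
    "run_lbp",
    "spedre_base",
]

_LOG_TINY = -745.0  # log of the smallest positive double, used as a -inf stand-in


@dataclass(frozen=True)
class ParameterBins:
    """Equidistant discretization of one parameter's domain.

    Bin b covers [lower + b*width, lower + (b+1)*width) and is represented by
    its midpoint lower + (b + 0.5)*width.
    """

    lower: float
    upper: float
    count: int

    def __post_init__(self) -> None:
        if self.count < 1:
            raise ValueError("bin count must be >= 1")
        if self.upper <= self.lower:
            raise ValueError("bin width must be positive (upper > lower)")
        if self.count == 1:
            warnings.warn("single-bin discretization is degenerate", RuntimeWarning)

    @property
    def width(self) -> float:
        return (self.upper - self.lower) / self.count

    @property
    def midpoints(self) -> np.ndarray:
        b = np.arange(self.count)
        return self.lower + (b + 0.5) * self.width


def build_bins(lower: float, upper: float, count: int) -> ParameterBins:
    """Equidistant bins on [lower, upper]; e.g. (0.05, 1.05, 10) -> midpoints 0.1..1.0."""
    return ParameterBins(float(lower), float(upper), int(count))


@dataclass
class DiscretizationScheme:
    """Per-parameter bins for a whole network."""

    bins: list[ParameterBins]

    @classmethod
    def uniform(cls, n_parameters: int, lower: float, upper: float, count: int) -> "DiscretizationScheme":
        return cls([build_bins(lower, upper, count) for _ in range(n_parameters)])

    def midpoints(self, param: int) -> np.ndarray:
        return self.bins[param].midpoints

    def midpoint_vector(self, bin_indices: np.ndarray) -> np.ndarray:
        return np.array(
            [self.bins[p].midpoints[b] for p, b in enumerate(bin_indices)], dtype=float
        )

    @property
    def n_parameters(self) -> int:
        return len(self.bins)


@dataclass
class JointTable:
    """Pre-computed joint probability table of one factor node.

    ``probs[b1, ..., bd]`` is the Boltzmann weight of the bin combination,
    normalized so the whole table sums to 1; axis order follows
    ``param_indices`` (ascending parameter index).
    """

    factor: ErrorTermIndex
    param_indices: tuple[int, ...]
    probs: np.ndarray
    log_probs: np.ndarray
    beta: float

    @property
    def size(self) -> int:
        return int(self.probs.size)


@dataclass
class FactorNode:
    index: ErrorTermIndex
    param_indices: tuple[int, ...]
    table: JointTable | None = None


@dataclass
class FactorGraph:
    """Bipartite graph of parameter variable nodes and error-term factor nodes."""

    network: ReactionNetwork
    scheme: DiscretizationScheme
    factors: list[FactorNode]
    var_factors: list[list[int]]  # per parameter: adjacent factor positions
    cells_computed: int = 0
    # message state, populated by run_lbp
    log_beliefs: list[np.ndarray] = field(default_factory=list)
    message_history: list[dict[int, np.ndarray]] = field(default_factory=list)

    @property
    def n_variables(self) -> int:
        return self.network.n_parameters


def build_factor_graph(
    network: ReactionNetwork,
    dataset: TimeSeriesDataset,
    scheme: DiscretizationScheme | None = None,
    *,
    include_boundary: bool = True,
) -> FactorGraph:
    """Construct the bipartite structure (no joint tables yet).

    One factor node per (experiment, species, timepoint) used; a factor is
    adjacent to parameter k iff k appears in that species' ODE.  With
    ``include_boundary=False`` the first and last timepoint of each experiment
    contribute no factors — the spline derivative estimates there carry the
    boundary-condition bias that the derivative table flags as unreliable.
    """
    if scheme is None:
        scheme = DiscretizationScheme.uniform(network.n_parameters, 0.05, 1.05, 10)
    if scheme.n_parameters != network.n_parameters:
        raise ValueError("discretization scheme does not match parameter count")
    per_species = [tuple(sorted(params_in_ode(network, i))) for i in range(network.n_species)]
    covered = set().union(*[set(p) for p in per_species]) if per_species else set()
    missing = set(range(network.n_parameters)) - covered
    if missing:
        names = [network.parameter_names[p] for p in sorted(missing)]
        raise ValueError(f"parameters {names} appear in no ODE (unidentifiable)")

    factors: list[FactorNode] = []
    var_factors: list[list[int]] = [[] for _ in range(network.n_parameters)]
    for e in range(dataset.n_experiments):
        n_t = dataset.timepoints[e].size
        j_range = range(n_t) if include_boundary or n_t < 3 else range(1, n_t - 1)
        for i in range(dataset.n_species):
            adj = per_species[i]
            if not adj:
                continue  # isolated species constrain nothing
            for j in j_range:
                pos = len(factors)
                factors.append(FactorNode(ErrorTermIndex(e, i, j), adj))
                for p in adj:
                    var_factors[p].append(pos)
    return FactorGraph(network=network, scheme=scheme, factors=factors, var_factors=var_factors)


def _grid_error_terms(
    factor: ErrorTermIndex,
    param_indices: tuple[int, ...],
    network: ReactionNetwork,
    derivs: DerivativeTable,
    scheme: DiscretizationScheme,
    form: str = "squared",
) -> np.ndarray:
    """epsilon_(e,i,j) evaluated at every bin-midpoint combination.

    Mass-action RHS terms are each linear in exactly one rate constant, so
    f_i over the grid is a sum of per-parameter coefficient * midpoint arrays
    broadcast along their own axis — every cell is still an exact evaluation.
    """
    e, i, j = factor
    conc = derivs.concentrations[e][j]
    lhs = derivs.derivatives[e][j, i]
    coefs = {p: 0.0 for p in param_indices}
    for r_pos, rxn in enumerate(network.reactions):
        if i not in rxn.reactant_indices and i not in rxn.product_indices:
            continue
        stoich = network._stoich[i, r_pos]
        flux = float(np.prod(conc[list(rxn.reactant_indices)]))
        coefs[rxn.parameter_index] += stoich * flux
    d = len(param_indices)
    rhs = np.zeros([scheme.bins[p].count for p in param_indices])
    for axis, p in enumerate(param_indices):
        shape = [1] * d
        shape[axis] = -1
        rhs = rhs + (coefs[p] * scheme.midpoints(p)).reshape(shape)
    resid = rhs - lhs
    return resid**2 if form == "squared" else np.abs(resid)


def compute_joint_table(
    factor: ErrorTermIndex,
    network: ReactionNetwork,
    dataset: TimeSeriesDataset,
    derivs: DerivativeTable,
    scheme: DiscretizationScheme,
    beta: float | None = None,
    *,
    form: str = "squared",
    param_indices: tuple[int, ...] | None = None,
) -> JointTable:
    """Boltzmann-weighted joint probability table for one factor node.

    cell(b) = C * exp(-beta * epsilon(midpoints(b))), with C normalizing the
    table to sum 1.  With ``beta=None`` the scale adapts to
    1 / max(median epsilon over this table, 1e-12), keeping the table neither
    flat nor one-hot; graph-level table construction
    (:func:`attach_joint_tables`) instead shares one global adaptive scale
    across factors so their relative weighting stays consistent.
    Normalization is done in log space, so a table whose raw weights all
    underflow still normalizes instead of erroring.
    """
    if param_indices is None:
        param_indices = tuple(sorted(params_in_ode(network, factor.species)))
    eps = _grid_error_terms(factor, param_indices, network, derivs, scheme, form)
    if beta is None:
        beta_val = 1.0 / max(float(np.median(eps)), 1e-12)
    else:
        if beta <= 0:
            raise ValueError("beta must be positive")
        beta_val = float(beta)
    logw = -beta_val * eps
    log_probs = logw - logsumexp(logw)
    return JointTable(
        factor=factor,
        param_indices=param_indices,
        probs=np.exp(log_probs),
        log_probs=log_probs,
        beta=beta_val,
    )


def attach_joint_tables(
    graph: FactorGraph,
    dataset: TimeSeriesDataset,
    derivs: DerivativeTable,
    beta: float | None = None,
    *,
    form: str = "squared",
) -> None:
    """Pre-compute every factor's table once (step A.1); counts grid cells.

    With ``beta=None`` a single global temperature, 1 / max(median of all grid
    error terms, 1e-12), is shared by every factor: a common scale keeps the
    relative weighting of factors consistent (so the max-product assignment
    tracks the product-of-errors objective) while still adapting the contrast
    to the problem's error magnitude.
    """
    grids = [
        _grid_error_terms(node.index, node.param_indices, graph.network, derivs,
                          graph.scheme, form)
        for node in graph.factors
    ]
    if beta is None:
        all_eps = np.concatenate([g.ravel() for g in grids])
        beta_val = 1.0 / max(float(np.median(all_eps)), 1e-12)
    else:
        if beta <= 0:
            raise ValueError("beta must be positive")
        beta_val = float(beta)
    cells = 0
    for node, eps in zip(graph.factors, grids):
        logw = -beta_val * eps
        log_probs = logw - logsumexp(logw)
        node.table = JointTable(
            factor=node.index,
            param_indices=node.param_indices,
            probs=np.exp(log_probs),
            log_probs=log_probs,
            beta=beta_val,
        )
        cells += node.table.size
    graph.cells_computed = cells


def table_argmax(table: JointTable) -> tuple[int, ...]:
    """Lexicographically-first maximizing bin combination of one table."""
    return tuple(int(b) for b in np.unravel_index(int(np.argmax(table.probs)), table.probs.shape))


def max_marginalize(g: np.ndarray, keep_dim: int) -> np.ndarray:
    """Maximize a non-negative array over every dimension except ``keep_dim``."""
    g = np.asarray(g)
    if not (0 <= keep_dim < g.ndim):
        raise ValueError("keep_dim out of range")
    axes = tuple(a for a in range(g.ndim) if a != keep_dim)
    return g.max(axis=axes) if axes else g.copy()


@dataclass
class MAPResult:
    """Outcome of loopy belief propagation: per-parameter MAP bins and beliefs."""

    bins: np.ndarray
    midpoints: np.ndarray
    beliefs: list[np.ndarray]
    converged: bool
    iterations: int
    message_deltas: list[float]
    weak_parameters: list[int] = field(default_factory=list)
    cells_computed: int = 0

    def to_dict(self, parameter_names: list[str] | None = None) -> dict:
        names = parameter_names or [f"k{p + 1}" for p in range(self.bins.size)]
        return {
            "converged": self.converged,
            "iterations": self.iterations,
            "cells_computed": self.cells_computed,
            "parameters": {
                name: {
                    "bin": int(self.bins[p]),
                    "midpoint": float(self.midpoints[p]),
                    "belief": [float(v) for v in self.beliefs[p]],
                }
                for p, name in enumerate(names)
            },
        }


def _normalize_log(v: np.ndarray) -> np.ndarray:
    return v - logsumexp(v)


def run_lbp(
    graph: FactorGraph,
    tol: float = 1e-6,
    max_iter: int = 100,
    *,
    damping: float = 0.0,
    standard_bp: bool = False,
) -> MAPResult:
    """Max-product loopy belief propagation on a prepared factor graph.

    Each iteration sweeps factors in fixed lexicographic order: every factor
    sends each adjacent variable a log-space message — the max-marginalization
    of (log table + incoming variable messages from the other variables) onto
    that variable's axis — which is normalized and stored in the recipient's
    message history.  Variables then update their beliefs to the normalized
    product of all stored incoming messages.  Iteration stops when no
    normalized message moves by more than ``tol`` (sup-norm) between
    iterations, or at ``max_iter`` (non-convergence is flagged, not an error:
    loopy propagation can oscillate on cyclic graphs).
    """
    if not graph.factors:
        raise ValueError("empty factor graph")
    if any(node.table is None for node in graph.factors):
        raise ValueError("joint tables must be computed before propagation")
    n_var = graph.n_variables
    counts = [graph.scheme.bins[p].count for p in range(n_var)]
    log_beliefs = [np.full(c, -np.log(c)) for c in counts]
    history: list[dict[int, np.ndarray]] = [{} for _ in range(n_var)]

    prev_flat: np.ndarray | None = None
    deltas: list[float] = []
    converged = False
    iteration = 0
    for iteration in range(1, max_iter + 1):
        # B.1: factor-to-variable messages
        for f_pos, node in enumerate(graph.factors):
            table = node.table
            adj = node.param_indices
            incoming = []
            for p in adj:
                if standard_bp:
                    prior = history[p].get(f_pos)
                    q = log_beliefs[p] if prior is None else _normalize_log(
                        np.maximum(log_beliefs[p], _LOG_TINY) - prior
                    )
                else:
                    q = log_beliefs[p]  # Box-1 variant: full current belief
                incoming.append(q)
            S = table.log_probs
            for axis, q in enumerate(incoming):
                shape = [1] * len(adj)
                shape[axis] = -1
                S = S + q.reshape(shape)
            for axis, p in enumerate(adj):
                other = tuple(a for a in range(len(adj)) if a != axis)
                msg = S.max(axis=other) if other else S.copy()
                msg = msg - incoming[axis]  # exclude the recipient's own message
                msg = _normalize_log(msg)
                if damping > 0 and f_pos in history[p]:
                    old = history[p][f_pos]
                    msg = _normalize_log(
                        np.log((1 - damping) * np.exp(msg) + damping * np.exp(old))
                    )
                history[p][f_pos] = msg
        # B.2: belief updates from the message history
        for p in range(n_var):
            if history[p]:
                total = np.sum([m for m in history[p].values()], axis=0)
                log_beliefs[p] = _normalize_log(total)
        flat = np.concatenate(
            [np.exp(history[p][f]) for p in range(n_var) for f in sorted(history[p])]
        )
        if prev_flat is not None:
            delta = float(np.max(np.abs(flat - prev_flat)))
            deltas.append(delta)
            if delta <= tol:
                converged = True
                break
        prev_flat = flat

    beliefs = [np.exp(lb) for lb in log_beliefs]
    bins = np.array([int(np.argmax(b)) for b in beliefs])  # ties -> lowest index
    weak = []
    for p, b in enumerate(beliefs):
        if b.size > 1:
            top2 = np.sort(b)[-2:]
            if top2[1] - top2[0] < 1e-3:
                weak.append(p)
    if weak:
        names = [graph.network.parameter_names[p] for p in weak]
        warnings.warn(
            f"weakly identified parameters (near-tied beliefs): {names}", RuntimeWarning
        )
    graph.log_beliefs = log_beliefs
    graph.message_history = history
    return MAPResult(
        bins=bins,
        midpoints=graph.scheme.midpoint_vector(bins),
        beliefs=beliefs,
        converged=converged,
        iterations=iteration,
        message_deltas=deltas,
        weak_parameters=weak,
        cells_computed=graph.cells_computed,
    )


def spedre_base(
    network: ReactionNetwork,
    dataset: TimeSeriesDataset,
    scheme: DiscretizationScheme,
    *,
    beta: float | None = None,
    tol: float = 1e-6,
    max_iter: int = 100,
    smoothing: float = 0.0,
    standard_bp: bool = False,
    damping: float = 0.0,
    form: str = "squared",
    derivs: DerivativeTable | None = None,
    use_boundary_timepoints: bool = False,
) -> MAPResult:
    """Discretized MAP estimation: splines -> error tables -> belief propagation.

    Deterministic given its inputs; returns the MAP bin midpoints that seed
    local refinement.  By default the first and last observation of each
    experiment contribute no factors: the spline derivative is least reliable
    there, and endpoint factors can pull the discrete optimum away from the
    data-generating bins.
    """
    if derivs is None:
        derivs = interpolated_derivatives(dataset, smoothing)
    graph = build_factor_graph(
        network, dataset, scheme, include_boundary=use_boundary_timepoints
    )
    attach_joint_tables(graph, dataset, derivs, beta, form=form)
    result = run_lbp(graph, tol=tol, max_iter=max_iter, damping=damping, standard_bp=standard_bp)
    return result
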