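"""Spline interpolation of observed time courses and derivative estimation.

Observed concentrations are fitted per (experiment, species) with a cubic
spline; the fitted curve's analytic derivative evaluated at the observation
timepoints supplies the left-hand sides of the collocation error terms.  With
``smoothing = 0`` the spline interpolates every point exactly (natural boundary
conditions by default); a positive smoothing factor switches to a smoothing
spline for noisy data.  Derivative estimates at the first and last timepoint
are flagged as boundary values, where spline derivatives are least reliable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.interpolate import CubicSpline, UnivariateSpline, make_interp_spline

from .network import Trajectory

__all__ = [
    "TimeSeriesDataset",
    "SplineFit",
    "DerivativeTable",
    "fit_spline",
    "interpolated_derivatives",
]


@dataclass
class TimeSeriesDataset:
    """Dense observations: every species at every timepoint of every experiment.

    ``observations[e]`` has shape (n_timepoints_e, n_species), column order
    matching ``species_names``.
    """

    species_names: list[str]
    experiments: list[str]
    timepoints: list[np.ndarray]
    observations: list[np.ndarray]

    def __post_init__(self) -> None:
        if not (len(self.experiments) == len(self.timepoints) == len(self.observations)):
            raise ValueError("experiments, timepoints and observations must align")
        self.timepoints = [np.asarray(t, dtype=float) for t in self.timepoints]
        self.observations = [np.asarray(x, dtype=float) for x in self.observations]
        n_s = len(self.species_names)
        for label, t, x in zip(self.experiments, self.timepoints, self.observations):
            if np.any(np.diff(t) <= 0):
                raise ValueError(f"experiment '{label}': timepoints not strictly increasing")
            if x.shape != (t.size, n_s) or not np.all(np.isfinite(x)):
                raise ValueError(
                    f"experiment '{label}': need a finite value for every species at "
                    "every timepoint (data-rich requirement violated)"
                )

    @property
    def n_experiments(self) -> int:
        return len(self.experiments)

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    def n_error_terms(self) -> int:
        return sum(t.size for t in self.timepoints) * self.n_species

    @classmethod
    def from_trajectories(
        cls,
        species_names: list[str],
        trajectories: list[Trajectory],
        labels: list[str] | None = None,
    ) -> "TimeSeriesDataset":
        labels = labels or [f"exp{e}" for e in range(len(trajectories))]
        return cls(
            species_names=list(species_names),
            experiments=labels,
            timepoints=[tr.timepoints for tr in trajectories],
            observations=[tr.values for tr in trajectories],
        )

    @classmethod
    def from_csvs(
        cls, paths: list[str | Path], labels: list[str] | None = None
    ) -> "TimeSeriesDataset":
        """Read one trajectory CSV per experiment (``time`` column + one per species)."""
        frames = [pd.read_csv(p) for p in paths]
        species = [c for c in frames[0].columns if c != "time"]
        for p, df in zip(paths, frames):
            if "time" not in df.columns:
                raise ValueError(f"{p}: missing 'time' column")
            missing = set(species) - set(df.columns)
            if missing:
                raise ValueError(
                    f"{p}: data-rich requirement violated, missing species {sorted(missing)}"
                )
        return cls(
            species_names=species,
            experiments=labels or [Path(p).stem for p in paths],
            timepoints=[df["time"].to_numpy(float) for df in frames],
            observations=[df[species].to_numpy(float) for df in frames],
        )

    def to_csv(self, experiment: int, path: str | Path) -> None:
        df = pd.DataFrame(self.observations[experiment], columns=self.species_names)
        df.insert(0, "time", self.timepoints[experiment])
        df.to_csv(path, index=False)


@dataclass
class SplineFit:
    """A fitted smooth curve over one observation window with its derivative."""

    spline: object
    t_min: float
    t_max: float

    def _check(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        if np.any(t < self.t_min - 1e-12) or np.any(t > self.t_max + 1e-12):
            raise ValueError(
                f"requested time outside observation window [{self.t_min}, {self.t_max}]; "
                "extrapolation is not supported"
            )
        return t

    def __call__(self, t: np.ndarray) -> np.ndarray:
        return np.asarray(self.spline(self._check(t)), dtype=float)

    def derivative(self, t: np.ndarray) -> np.ndarray:
        return np.asarray(self.spline.derivative()(self._check(t)), dtype=float)


def fit_spline(
    times: np.ndarray,
    values: np.ndarray,
    smoothing: float = 0.0,
    *,
    bc_type: str = "natural",
) -> SplineFit:
    """Fit a cubic spline through one species' time course.

    smoothing = 0 gives an interpolating spline (passes through every point);
    smoothing > 0 gives a smoothing spline with that residual budget.  Fewer
    than 4 points fall back to the highest interpolable order.
    """
    t = np.asarray(times, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 2:
        raise ValueError("need at least 2 points to fit a spline")
    if np.unique(t).size != t.size:
        raise ValueError("duplicate times in spline input")
    if smoothing < 0:
        raise ValueError("smoothing must be non-negative")

    if smoothing > 0 and t.size >= 4:
        sp = UnivariateSpline(t, y, k=3, s=float(smoothing))
    elif t.size >= 4:
        sp = CubicSpline(t, y, bc_type=bc_type)
    else:
        sp = make_interp_spline(t, y, k=t.size - 1)
    return SplineFit(spline=sp, t_min=float(t[0]), t_max=float(t[-1]))


@dataclass
class DerivativeTable:
    """Interpolated derivatives (and smoothed concentrations) per experiment.

    ``derivatives[e]`` and ``concentrations[e]`` have shape
    (n_timepoints_e, n_species); ``boundary[e]`` flags the first and last
    timepoint, where the spline derivative is least trustworthy.  With
    smoothing = 0 the concentrations equal the raw observations.
    """

    derivatives: list[np.ndarray]
    concentrations: list[np.ndarray]
    boundary: list[np.ndarray] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.boundary:
            for d in self.derivatives:
                flag = np.zeros(d.shape[0], dtype=bool)
                flag[0] = flag[-1] = True
                self.boundary.append(flag)

    def to_csv(self, dataset: TimeSeriesDataset, experiment: int, path: str | Path) -> None:
        df = pd.DataFrame(
            self.derivatives[experiment],
            columns=[f"{s}_ddt" for s in dataset.species_names],
        )
        df.insert(0, "time", dataset.timepoints[experiment])
        df.to_csv(path, index=False)


def interpolated_derivatives(
    dataset: TimeSeriesDataset,
    smoothing: float = 0.0,
    *,
    bc_type: str = "natural",
) -> DerivativeTable:
    """Spline-fit every (experiment, species) series and tabulate derivatives."""
    derivs: list[np.ndarray] = []
    concs: list[np.ndarray] = []
    for e in range(dataset.n_experiments):
        t = dataset.timepoints[e]
        d = np.empty((t.size, dataset.n_species))
        c = np.empty_like(d)
        for i in range(dataset.n_species):
            fit = fit_spline(t, dataset.observations[e][:, i], smoothing, bc_type=bc_type)
            d[:, i] = fit.derivative(t)
            c[:, i] = fit(t) if smoothing > 0 else dataset.observations[e][:, i]
        if not np.all(np.isfinite(d)):
            warnings.warn("non-finite interpolated derivative encountered", RuntimeWarning)
        derivs.append(d)
        concs.append(c)
    return DerivativeTable(derivatives=derivs, concentrations=concs)
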