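"""Synthetic benchmark problems: ring networks, random low-degree networks,
an Akt-pathway topology, and noisy dataset generation.

These generators produce every input the estimation pipeline is evaluated on,
fully determined by a seed.  The canonical small-scale setup is a ring of
unimolecular conversions observed at 11 timepoints over 4 s (0.4 s steps),
with each rate constant discretized into 10 equidistant bins on [0.05, 1.05]
and nominal rates optionally snapped to bin midpoints so that exact bin
recovery is well defined.  Noise is multiplicative Gaussian,
x_obs = x·(1 + level·z), z ~ N(0,1), clipped at zero; percentage noise levels
imply relative perturbations.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .factor_graph import DiscretizationScheme
from .network import Reaction, ReactionNetwork, ode_degree, simulate
from .splines import TimeSeriesDataset

__all__ = [
    "BenchmarkScenario",
    "make_ring_network",
    "make_random_low_degree_network",
    "make_akt_network",
    "generate_dataset",
    "snap_to_midpoints",
    "canonical_timepoints",
    "canonical_scheme",
    "make_ring_scenario",
    "make_random_scenario",
    "make_akt_scenario",
]


def canonical_timepoints(n_t: int = 11, duration: float = 4.0) -> np.ndarray:
    """The canonical observation grid: n_t equidistant points on [0, duration] s."""
    return np.linspace(0.0, duration, n_t)


def canonical_scheme(n_parameters: int, count: int = 10,
                     lower: float = 0.05, upper: float = 1.05) -> DiscretizationScheme:
    """10 equidistant bins on [0.05, 1.05] per parameter (midpoints 0.1 ... 1.0)."""
    return DiscretizationScheme.uniform(n_parameters, lower, upper, count)


@dataclass(frozen=True)
class BenchmarkScenario:
    """A fully seeded estimation problem: network, truth, grid, noise."""

    network: ReactionNetwork
    nominal_params: np.ndarray
    timepoints: np.ndarray
    noise_level: float = 0.0
    seed: int = 0
    n_experiments: int = 1
    initial_concentrations: np.ndarray | None = None  # per experiment, else seeded U[0.1, 1]


def snap_to_midpoints(params: np.ndarray, scheme: DiscretizationScheme) -> np.ndarray:
    """Replace each rate constant by the midpoint of its nearest bin."""
    out = np.empty_like(np.asarray(params, dtype=float))
    for p, k in enumerate(params):
        mids = scheme.midpoints(p)
        out[p] = mids[int(np.argmin(np.abs(mids - k)))]
    return out


def make_ring_network(n: int) -> ReactionNetwork:
    """Cycle of unimolecular conversions A1 -> A2 -> ... -> An -> A1.

    Every species has one inflow and one outflow reaction, so every ODE has
    degree 2 regardless of ring size.
    """
    if n < 2:
        raise ValueError("a ring needs at least 2 species")
    reactions = [
        Reaction(reactant_indices=(i,), product_indices=((i + 1) % n,), parameter_index=i)
        for i in range(n)
    ]
    return ReactionNetwork(
        species_names=[f"A{i + 1}" for i in range(n)],
        reactions=reactions,
        parameter_names=[f"k{i + 1}" for i in range(n)],
    )


def make_random_low_degree_network(
    n_species: int,
    n_reactions: int | None = None,
    seed: int = 0,
    *,
    max_degree: int = 4,
    max_tries: int = 2000,
) -> ReactionNetwork:
    """Random connected low-degree network: 2/3 bimolecular, 1/3 unimolecular.

    round(2/3·n_reactions) reactions are A + B -> C over three distinct
    species and the rest are conversions A -> B; each reaction gets its own
    rate constant.  Sampling rejects duplicate reactions (two copies of the
    same conversion would leave only the sum of their rate constants
    identifiable) and reactions that would push any species' ODE degree above
    ``max_degree``, and resamples whole networks until every species
    participates in at least one reaction.
    """
    if n_species < 3 or (n_reactions is not None and n_reactions < 3):
        raise ValueError("need at least 3 species and 3 reactions")
    if n_reactions is None:
        n_reactions = n_species
    n_bi = round(2 * n_reactions / 3)
    rng = np.random.default_rng(seed)

    for _ in range(max_tries):
        degree = np.zeros(n_species, dtype=int)
        reactions: list[Reaction] = []
        seen: set = set()
        ok = True
        for r in range(n_reactions):
            placed = False
            for _attempt in range(200):
                if r < n_bi:
                    a, b, c = rng.choice(n_species, size=3, replace=False)
                    touched = (int(a), int(b), int(c))
                    key = (frozenset((int(a), int(b))), int(c))
                    cand = Reaction((int(a), int(b)), (int(c),), r)
                else:
                    a, b = rng.choice(n_species, size=2, replace=False)
                    touched = (int(a), int(b))
                    key = (int(a), int(b))
                    cand = Reaction((int(a),), (int(b),), r)
                if key not in seen and all(degree[t] < max_degree for t in touched):
                    seen.add(key)
                    for t in touched:
                        degree[t] += 1
                    reactions.append(cand)
                    placed = True
                    break
            if not placed:
                ok = False
                break
        if ok and np.all(degree > 0):
            return ReactionNetwork(
                species_names=[f"S{i + 1}" for i in range(n_species)],
                reactions=reactions,
                parameter_names=[f"k{r + 1}" for r in range(n_reactions)],
            )
    raise RuntimeError(
        f"could not sample a connected degree<={max_degree} network "
        f"with {n_species} species and {n_reactions} reactions"
    )


_AKT_MODEL = """\
# Akt activation topology with redox regulation of PTEN.
# Serum drives PI3K activation and NOX-dependent ROS production; ROS
# reversibly inactivate PTEN; PI3K and PTEN set the PIP2/PIP3 balance;
# PIP3 recruits Akt and PDK1 to the membrane, where PDK1 phosphorylates
# Akt at Thr308; phospho-Akt returns to the cytosol and PP2A removes
# the phosphate.  Catalysts appear on both sides (mass action).
serum + inactPI3K -> serum + PI3K ; k_pi3k_act
PI3K -> inactPI3K ; k_pi3k_deact
NOX + serum -> NOX + ROS ; k_ros_prod
ROS -> ; k_ros_deg
ROS + PTEN -> ROS + inactPTEN ; k_pten_inact
inactPTEN -> PTEN ; k_pten_react
PI3K + PIP2 -> PI3K + PIP3 ; k_pip3_prod
PTEN + PIP3 -> PTEN + PIP2 ; k_pip3_deg
PIP3 + Akt_cyto -> PIP3 + Akt_mem ; k_akt_rec
Akt_mem -> Akt_cyto ; k_akt_rel
PIP3 + PDK1_cyto -> PIP3 + PDK1_mem ; k_pdk1_rec
PDK1_mem -> PDK1_cyto ; k_pdk1_rel
PDK1_mem + Akt_mem -> PDK1_mem + Akt_p308_mem ; k_akt_phos
Akt_p308_mem -> Akt_p308_cyto ; k_akt_ret
PP2A + Akt_p308_cyto -> PP2A + Akt_cyto ; k_akt_dephos
"""

# Unit-scale placeholder rate constants (the published kinetic values are not
# reproduced here); overridable via make_akt_network(rates=...).
_AKT_DEFAULT_RATES = {
    "k_pi3k_act": 0.9,
    "k_pi3k_deact": 0.3,
    "k_ros_prod": 0.7,
    "k_ros_deg": 0.4,
    "k_pten_inact": 0.8,
    "k_pten_react": 0.2,
    "k_pip3_prod": 1.0,
    "k_pip3_deg": 0.9,
    "k_akt_rec": 0.8,
    "k_akt_rel": 0.3,
    "k_pdk1_rec": 0.6,
    "k_pdk1_rel": 0.25,
    "k_akt_phos": 0.9,
    "k_akt_ret": 0.5,
    "k_akt_dephos": 0.6,
}


def make_akt_network(
    rates: dict[str, float] | None = None,
) -> tuple[ReactionNetwork, np.ndarray]:
    """The Akt signalling topology with placeholder nominal rate constants.

    Returns (network, nominal parameter vector).  The topology covers
    serum-driven PI3K activation, NOX/ROS production and antioxidant decay,
    reversible redox inactivation of PTEN, the PIP2/PIP3 cycle,
    PIP3-dependent membrane recruitment of Akt and PDK1, Thr308
    phosphorylation, return to the cytosol and PP2A dephosphorylation.  Rate
    constants default to fixed unit-scale placeholders and can be overridden
    per parameter name.
    """
    from .network import parse_network

    net = parse_network(_AKT_MODEL)
    values = dict(_AKT_DEFAULT_RATES)
    if rates:
        unknown = set(rates) - set(values)
        if unknown:
            raise ValueError(f"unknown Akt rate names: {sorted(unknown)}")
        values.update(rates)
    nominal = np.array([values[name] for name in net.parameter_names])
    return net, nominal


def generate_dataset(scenario: BenchmarkScenario) -> TimeSeriesDataset:
    """Simulate the scenario and apply seeded multiplicative Gaussian noise.

    Initial concentrations default to U[0.1, 1.0] draws per experiment from
    the scenario seed; noise level 0 returns the simulation exactly.
    """
    rng = np.random.default_rng(scenario.seed)
    trajectories = []
    for e in range(scenario.n_experiments):
        if scenario.initial_concentrations is not None:
            x0 = np.atleast_2d(scenario.initial_concentrations)[e]
        else:
            x0 = rng.uniform(0.1, 1.0, size=scenario.network.n_species)
        traj = simulate(scenario.network, scenario.nominal_params, x0, scenario.timepoints)
        values = traj.values
        if scenario.noise_level > 0:
            z = rng.standard_normal(values.shape)
            values = np.clip(values * (1.0 + scenario.noise_level * z), 0.0, None)
        trajectories.append(values)
    return TimeSeriesDataset(
        species_names=list(scenario.network.species_names),
        experiments=[f"exp{e}" for e in range(scenario.n_experiments)],
        timepoints=[scenario.timepoints.copy() for _ in range(scenario.n_experiments)],
        observations=trajectories,
    )


def _seeded_nominal(
    n: int, scheme: DiscretizationScheme, seed: int, snap: bool
) -> np.ndarray:
    rng = np.random.default_rng(seed)
    lo = min(b.lower for b in scheme.bins)
    hi = max(b.upper for b in scheme.bins)
    params = rng.uniform(lo + 0.05 * (hi - lo), hi - 0.05 * (hi - lo), size=n)
    return snap_to_midpoints(params, scheme) if snap else params


def make_ring_scenario(
    n: int,
    *,
    n_t: int = 11,
    duration: float = 4.0,
    noise_level: float = 0.0,
    seed: int = 0,
    snap: bool = True,
    scheme: DiscretizationScheme | None = None,
) -> tuple[BenchmarkScenario, DiscretizationScheme]:
    """Ring-network estimation problem in the canonical small-scale setup."""
    net = make_ring_network(n)
    scheme = scheme or canonical_scheme(net.n_parameters)
    nominal = _seeded_nominal(net.n_parameters, scheme, seed, snap)
    scenario = BenchmarkScenario(
        network=net,
        nominal_params=nominal,
        timepoints=canonical_timepoints(n_t, duration),
        noise_level=noise_level,
        seed=seed,
    )
    return scenario, scheme


def make_random_scenario(
    n_species: int,
    *,
    n_reactions: int | None = None,
    n_t: int = 11,
    duration: float = 4.0,
    noise_level: float = 0.0,
    seed: int = 0,
    snap: bool = False,
    scheme: DiscretizationScheme | None = None,
) -> tuple[BenchmarkScenario, DiscretizationScheme]:
    """Random low-degree network problem; nominal rates random (not snapped)."""
    net = make_random_low_degree_network(n_species, n_reactions, seed)
    scheme = scheme or canonical_scheme(net.n_parameters)
    nominal = _seeded_nominal(net.n_parameters, scheme, seed + 1, snap)
    scenario = BenchmarkScenario(
        network=net,
        nominal_params=nominal,
        timepoints=canonical_timepoints(n_t, duration),
        noise_level=noise_level,
        seed=seed,
    )
    return scenario, scheme


def make_akt_scenario(
    *,
    noise_level: float = 0.0,
    n_t: int = 11,
    duration: float = 4.0,
    seed: int = 0,
    scheme: DiscretizationScheme | None = None,
) -> tuple[BenchmarkScenario, DiscretizationScheme]:
    """Akt-topology estimation problem with the placeholder nominal rates."""
    net, nominal = make_akt_network()
    scheme = scheme or canonical_scheme(net.n_parameters)
    scenario = BenchmarkScenario(
        network=net,
        nominal_params=nominal,
        timepoints=canonical_timepoints(n_t, duration),
        noise_level=noise_level,
        seed=seed,
    )
    return scenario, scheme


def with_noise(scenario: BenchmarkScenario, noise_level: float) -> BenchmarkScenario:
    """Same scenario (same seed, truth, grid) at a different noise level."""
    return replace(scenario, noise_level=noise_level)


def network_degree_ok(network: ReactionNetwork, cap: int = 4) -> bool:
    return max(ode_degree(network, i) for i in range(network.n_species)) <= cap
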