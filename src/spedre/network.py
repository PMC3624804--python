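"""Mass-action reaction networks: parsing, ODE right-hand sides, and simulation.

A network is a list of elementary mass-action reactions, each carrying exactly
one rate parameter.  The ODE for species ``i`` is the sum over reactions of
``±k * prod(reactant concentrations)`` — minus when ``i`` is consumed, plus when
it is produced.  The *degree* of an ODE is the number of reactions touching the
species (each touching reaction contributes one right-hand-side term); the
network degree, the maximum over species, bounds the cost of downstream
factor-graph inference.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

__all__ = [
    "Reaction",
    "ReactionNetwork",
    "Trajectory",
    "NetworkParseError",
    "SimulationError",
    "parse_network",
    "ode_rhs",
    "ode_degree",
    "params_in_ode",
    "simulate",
]


class NetworkParseError(ValueError):
    """Raised for syntactically invalid reaction-list text."""


class SimulationError(RuntimeError):
    """Raised when numerical integration of the ODE system fails."""


@dataclass(frozen=True)
class Reaction:
    """One elementary mass-action reaction.

    rate = k[parameter_index] * prod(concentration of each reactant entry);
    a species listed twice as reactant contributes its concentration squared.
    """

    reactant_indices: tuple[int, ...]
    product_indices: tuple[int, ...]
    parameter_index: int

    def __post_init__(self) -> None:
        if not (1 <= len(self.reactant_indices) <= 2):
            raise ValueError("a reaction needs 1 or 2 reactant entries")
        if len(self.product_indices) > 2:
            raise ValueError("a reaction may have at most 2 product entries")
        if self.parameter_index < 0:
            raise ValueError("parameter_index must be non-negative")


@dataclass
class ReactionNetwork:
    """Species, reactions, and the parameter-to-ODE incidence structure."""

    species_names: list[str]
    reactions: list[Reaction]
    parameter_names: list[str] = field(default_factory=list)

    # vectorized evaluation scaffolding, built once
    _stoich: np.ndarray = field(init=False, repr=False)
    _r1: np.ndarray = field(init=False, repr=False)
    _r2: np.ndarray = field(init=False, repr=False)
    _pidx: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        n_s = len(self.species_names)
        if not self.reactions:
            raise ValueError("network has no reactions")
        if not self.parameter_names:
            self.parameter_names = [f"k{r.parameter_index + 1}" for r in self.reactions]
            # dedupe while keeping index order
            self.parameter_names = [f"k{i + 1}" for i in range(self.n_parameters)]
        for rxn in self.reactions:
            for idx in rxn.reactant_indices + rxn.product_indices:
                if not (0 <= idx < n_s):
                    raise ValueError(f"species index {idx} out of range")
        used = {r.parameter_index for r in self.reactions}
        if used != set(range(self.n_parameters)):
            raise ValueError("every parameter index in [0, n_parameters) must be used")

        n_r = len(self.reactions)
        S = np.zeros((n_s, n_r))
        r1 = np.zeros(n_r, dtype=int)
        r2 = np.full(n_r, -1, dtype=int)
        pidx = np.zeros(n_r, dtype=int)
        for j, rxn in enumerate(self.reactions):
            for i in rxn.reactant_indices:
                S[i, j] -= 1.0
            for i in rxn.product_indices:
                S[i, j] += 1.0
            r1[j] = rxn.reactant_indices[0]
            if len(rxn.reactant_indices) == 2:
                r2[j] = rxn.reactant_indices[1]
            pidx[j] = rxn.parameter_index
        self._stoich = S
        self._r1 = r1
        self._r2 = r2
        self._pidx = pidx

    @property
    def n_species(self) -> int:
        return len(self.species_names)

    @property
    def n_parameters(self) -> int:
        return max(r.parameter_index for r in self.reactions) + 1

    def reaction_rates(self, params: np.ndarray, state: np.ndarray) -> np.ndarray:
        """Mass-action rate of every reaction at the given state."""
        rates = params[self._pidx] * state[self._r1]
        second = self._r2 >= 0
        rates[second] *= state[self._r2[second]]
        return rates

    def degree(self) -> int:
        """Network degree: max over species of the ODE degree."""
        return max(ode_degree(self, i) for i in range(self.n_species))


@dataclass(frozen=True)
class Trajectory:
    """Time course of all species concentrations."""

    timepoints: np.ndarray
    values: np.ndarray  # shape (n_timepoints, n_species)

    def __post_init__(self) -> None:
        t = np.asarray(self.timepoints, dtype=float)
        v = np.asarray(self.values, dtype=float)
        if np.any(np.diff(t) <= 0):
            raise ValueError("timepoints must be strictly increasing")
        if not np.all(np.isfinite(v)):
            raise ValueError("trajectory contains non-finite concentrations")
        object.__setattr__(self, "timepoints", t)
        object.__setattr__(self, "values", v)


def parse_network(model_text: str) -> ReactionNetwork:
    """Parse a reaction-list model.

    Format (one reaction per line)::

        <reactants> -> <products> ; <param_name>

    Reactants/products are ``+``-separated species names; the product side may
    be empty (degradation).  ``#`` starts a comment, blank lines are ignored.
    Species are registered in order of first appearance; reusing a parameter
    name binds the same rate constant to several reactions.
    """
    species: dict[str, int] = {}
    params: dict[str, int] = {}
    reactions: list[Reaction] = []

    def species_id(name: str) -> int:
        if name not in species:
            species[name] = len(species)
        return species[name]

    for lineno, raw in enumerate(model_text.splitlines(), start=1):
        line = raw.split("#", 1)[0].strip()
        if not line:
            continue
        if ";" not in line or "->" not in line:
            raise NetworkParseError(f"line {lineno}: expected '<lhs> -> <rhs> ; <param>'")
        body, pname = line.rsplit(";", 1)
        pname = pname.strip()
        if not pname:
            raise NetworkParseError(f"line {lineno}: missing parameter name")
        lhs, _, rhs = body.partition("->")

        def side(text: str, allow_empty: bool) -> list[str]:
            names = [s.strip() for s in text.split("+") if s.strip()]
            if not names and not allow_empty:
                raise NetworkParseError(f"line {lineno}: empty reactant side")
            return names

        reactants = side(lhs, allow_empty=False)
        products = side(rhs, allow_empty=True)
        if len(reactants) > 2 or len(products) > 2:
            raise NetworkParseError(f"line {lineno}: at most 2 reactants and 2 products")
        if pname not in params:
            params[pname] = len(params)
        reactions.append(
            Reaction(
                reactant_indices=tuple(species_id(s) for s in reactants),
                product_indices=tuple(species_id(s) for s in products),
                parameter_index=params[pname],
            )
        )

    if not reactions:
        raise NetworkParseError("no reactions in model text")
    return ReactionNetwork(
        species_names=list(species),
        reactions=reactions,
        parameter_names=list(params),
    )


def ode_rhs(network: ReactionNetwork, params: np.ndarray, state: np.ndarray) -> np.ndarray:
    """Evaluate every species' time derivative at one state."""
    params = np.asarray(params, dtype=float)
    state = np.asarray(state, dtype=float)
    if params.shape != (network.n_parameters,):
        raise ValueError(f"expected {network.n_parameters} parameters, got {params.shape}")
    if state.shape != (network.n_species,):
        raise ValueError(f"expected {network.n_species} concentrations, got {state.shape}")
    return network._stoich @ network.reaction_rates(params, state)


def ode_degree(network: ReactionNetwork, species_index: int) -> int:
    """Number of right-hand-side terms of one species' ODE.

    Each reaction in which the species appears (as reactant or product)
    contributes one term; a purely catalytic appearance still counts once.
    """
    if not (0 <= species_index < network.n_species):
        raise ValueError("species index out of range")
    return sum(
        1
        for r in network.reactions
        if species_index in r.reactant_indices or species_index in r.product_indices
    )


def params_in_ode(network: ReactionNetwork, species_index: int) -> set[int]:
    """Rate-parameter indices appearing in one species' ODE."""
    if not (0 <= species_index < network.n_species):
        raise ValueError("species index out of range")
    return {
        r.parameter_index
        for r in network.reactions
        if species_index in r.reactant_indices or species_index in r.product_indices
    }


def simulate(
    network: ReactionNetwork,
    params: np.ndarray,
    initial: np.ndarray,
    timepoints: np.ndarray,
    *,
    rtol: float = 1e-8,
    atol: float = 1e-10,
) -> Trajectory:
    """Integrate the mass-action ODE system and sample it at ``timepoints``.

    A stiff-capable adaptive solver (LSODA) is used with tight default
    tolerances so that generated data carry negligible integration error
    relative to estimation error.
    """
    params = np.asarray(params, dtype=float)
    initial = np.asarray(initial, dtype=float)
    t = np.asarray(timepoints, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("timepoints must be strictly increasing")
    if np.any(initial < 0):
        raise ValueError("initial concentrations must be non-negative")
    if initial.shape != (network.n_species,):
        raise ValueError("initial condition has wrong length")

    def fun(_t: float, y: np.ndarray) -> np.ndarray:
        return network._stoich @ network.reaction_rates(params, y)

    sol = solve_ivp(
        fun, (t[0], t[-1]), initial, t_eval=t, method="LSODA", rtol=rtol, atol=atol
    )
    if not sol.success or not np.all(np.isfinite(sol.y)):
        bad_t = sol.t[-1] if sol.t.size else t[0]
        if sol.y.size:
            col = sol.y[:, -1]
            bad_i = int(np.argmax(~np.isfinite(col)) if not np.all(np.isfinite(col)) else np.argmax(np.abs(col)))
        else:
            bad_i = 0
        raise SimulationError(
            f"integration failed near t={bad_t:g} (species '{network.species_names[bad_i]}'): "
            f"{sol.message}"
        )
    return Trajectory(timepoints=t, values=sol.y.T.copy())
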