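"""Reaction-network data model shared by every simulation engine.

A network is a list of species and a list of reactions.  Each reaction
carries three per-species integer vectors:

``reactant_counts``
    molecules consumed per firing (determines the mass-action order),
``s_column``
    net change applied at the instant the reaction fires,
``s_delay_column``
    net change applied when the reaction *completes*, a delay ``tau``
    after firing.

Stacked over reactions these become the reactant matrix and the two
stoichiometric matrices (immediate and delayed) of shape
``(n_species, n_reactions)``.

Delayed reactions come in two classes.  A *consuming* reaction adjusts
state twice: ``s_column`` at firing, ``s_delay_column`` at completion
(e.g. reactants removed now, products appear after ``tau``).  A
*completion-only* reaction defers every change to the completion time;
its ``s_column`` must be all zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Callable, Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "DelayKind",
    "DelaySpec",
    "SpeciesSet",
    "Reaction",
    "ReactionNetwork",
    "SystemState",
    "build_network",
    "make_reaction",
    "mass_action_propensity",
    "evaluate_propensities",
    "apply_change",
    "NetworkValidationError",
    "PropensityError",
]


class NetworkValidationError(ValueError):
    """Raised when a network or reaction violates a structural invariant."""


class PropensityError(ValueError):
    """Raised when a custom propensity evaluates to a negative or non-finite value."""


class DelayKind(str, Enum):
    NONE = "none"
    CONSUMING = "consuming"
    COMPLETION_ONLY = "completion_only"


@dataclass(frozen=True)
class DelaySpec:
    """Delay class and delay-time generator for one reaction.

    ``delay`` is either a nonnegative constant (model time units) or a
    callable ``rng -> float`` drawn fresh at every firing.
    """

    kind: DelayKind = DelayKind.NONE
    delay: float | Callable[[np.random.Generator], float] | None = None

    def __post_init__(self) -> None:
        kind = DelayKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if kind is DelayKind.NONE:
            if self.delay is not None:
                raise NetworkValidationError("non-delayed reaction must not carry a delay value")
        else:
            if self.delay is None:
                raise NetworkValidationError(f"{kind.value} reaction requires a delay")
            if not callable(self.delay) and float(self.delay) < 0:
                raise NetworkValidationError("constant delay must be >= 0")

    @staticmethod
    def none() -> "DelaySpec":
        return DelaySpec(DelayKind.NONE, None)

    @staticmethod
    def consuming(delay) -> "DelaySpec":
        return DelaySpec(DelayKind.CONSUMING, delay)

    @staticmethod
    def completion_only(delay) -> "DelaySpec":
        return DelaySpec(DelayKind.COMPLETION_ONLY, delay)

    def draw(self, rng: np.random.Generator) -> float:
        """Sample one delay time (constant specs simply return the constant)."""
        if self.kind is DelayKind.NONE:
            raise ValueError("cannot draw a delay from a non-delayed spec")
        tau = self.delay(rng) if callable(self.delay) else float(self.delay)
        if tau < 0 or not math.isfinite(tau):
            raise ValueError(f"delay sampler returned invalid tau={tau!r}")
        return tau


@dataclass(frozen=True)
class SpeciesSet:
    """Ordered, unique species identifiers; the row axis of all matrices."""

    names: tuple[str, ...]

    def __post_init__(self) -> None:
        names = tuple(str(n) for n in self.names)
        if len(names) == 0:
            raise NetworkValidationError("at least one species is required")
        if any(n == "" for n in names):
            raise NetworkValidationError("species names must be non-empty")
        if len(set(names)) != len(names):
            raise NetworkValidationError("species names must be unique")
        object.__setattr__(self, "names", names)

    @property
    def size(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def _as_int_vector(v, n: int, what: str) -> np.ndarray:
    arr = np.asarray(v, dtype=np.int64)
    if arr.shape != (n,):
        raise NetworkValidationError(f"{what} must have length {n}, got shape {arr.shape}")
    return arr


@dataclass
class Reaction:
    """One reaction channel.

    Propensity is mass-action (``rate_constant`` times the combinatorial
    count of reactant tuples) unless ``custom_propensity`` is given, in
    which case that function of the per-species counts is used verbatim.
    """

    reactant_counts: np.ndarray
    s_column: np.ndarray
    s_delay_column: np.ndarray
    rate_constant: float | None = None
    custom_propensity: Optional[Callable[[Sequence[int]], float]] = None
    delay: DelaySpec = field(default_factory=DelaySpec.none)
    name: str = ""

    @property
    def propensity_rule(self) -> str:
        return "custom" if self.custom_propensity is not None else "mass_action"

    def validate(self, n_species: int, index: int) -> None:
        label = self.name or f"reaction[{index}]"
        self.reactant_counts = _as_int_vector(self.reactant_counts, n_species,
                                              f"{label}.reactant_counts")
        self.s_column = _as_int_vector(self.s_column, n_species, f"{label}.s_column")
        self.s_delay_column = _as_int_vector(self.s_delay_column, n_species,
                                             f"{label}.s_delay_column")
        if (self.reactant_counts < 0).any():
            raise NetworkValidationError(f"{label}: reactant counts must be >= 0")
        if self.custom_propensity is None:
            if self.rate_constant is None:
                raise NetworkValidationError(f"{label}: mass-action reaction needs a rate constant")
            if self.rate_constant < 0:
                raise NetworkValidationError(f"{label}: rate constant must be >= 0")
        if self.delay.kind is DelayKind.NONE and self.s_delay_column.any():
            raise NetworkValidationError(
                f"{label}: non-delayed reaction must have an all-zero s_delay_column")
        if self.delay.kind is DelayKind.COMPLETION_ONLY and self.s_column.any():
            raise NetworkValidationError(
                f"{label}: completion_only reaction defers all change; s_column must be zero")


def make_reaction(
    species: SpeciesSet,
    reactants: dict[str, int],
    products: dict[str, int],
    rate: float | None = None,
    propensity: Optional[Callable[[Sequence[int]], float]] = None,
    delay: DelaySpec | None = None,
    name: str = "",
) -> Reaction:
    """Build a reaction from reactant/product count maps.

    For a non-delayed reaction the net change is ``products - reactants``
    applied at firing.  A consuming delayed reaction removes reactants at
    firing and adds products at completion; a completion-only reaction
    applies ``products - reactants`` entirely at completion.
    """
    delay = delay or DelaySpec.none()
    n = species.size
    for nm in list(reactants) + list(products):
        if nm not in species.names:
            raise NetworkValidationError(f"undeclared species {nm!r} in reaction {name or '?'}")
    r_vec = np.zeros(n, dtype=np.int64)
    p_vec = np.zeros(n, dtype=np.int64)
    for nm, c in reactants.items():
        r_vec[species.index(nm)] = c
    for nm, c in products.items():
        p_vec[species.index(nm)] = c
    if delay.kind is DelayKind.NONE:
        s, sd = p_vec - r_vec, np.zeros(n, dtype=np.int64)
    elif delay.kind is DelayKind.CONSUMING:
        s, sd = -r_vec, p_vec
    else:  # completion_only
        s, sd = np.zeros(n, dtype=np.int64), p_vec - r_vec
    return Reaction(reactant_counts=r_vec, s_column=s, s_delay_column=sd,
                    rate_constant=rate, custom_propensity=propensity, delay=delay, name=name)


@dataclass
class ReactionNetwork:
    species: SpeciesSet
    reactions: list[Reaction]

    @property
    def n_species(self) -> int:
        return self.species.size

    @property
    def n_reactions(self) -> int:
        return len(self.reactions)

    @property
    def reactant_matrix(self) -> np.ndarray:
        return np.stack([r.reactant_counts for r in self.reactions], axis=1)

    @property
    def S_matrix(self) -> np.ndarray:
        return np.stack([r.s_column for r in self.reactions], axis=1)

    @property
    def S_matrix_delay(self) -> np.ndarray:
        return np.stack([r.s_delay_column for r in self.reactions], axis=1)

    @property
    def has_delays(self) -> bool:
        return any(r.delay.kind is not DelayKind.NONE for r in self.reactions)

    def species_index(self, name: str) -> int:
        return self.species.index(name)


def build_network(species: SpeciesSet, reactions: Iterable[Reaction]) -> ReactionNetwork:
    """Validate all components and return the assembled network."""
    reactions = list(reactions)
    if not reactions:
        raise NetworkValidationError("a network needs at least one reaction")
    for i, r in enumerate(reactions):
        r.validate(species.size, i)
    return ReactionNetwork(species=species, reactions=reactions)


@dataclass
class SystemState:
    """Molecule counts at a point in continuous time."""

    t: float
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.t < 0:
            raise ValueError("time must be >= 0")
        if (self.counts < 0).any():
            raise ValueError("molecule counts must be >= 0")


def mass_action_propensity(reaction: Reaction, counts: Sequence[int]) -> float:
    """Stochastic mass-action propensity, combinatorial convention.

    ``c * prod_i C(n_i, nu_i)``: a second-order ``2X -> ...`` channel at
    ``n`` copies has propensity ``c * n*(n-1)/2``, matching chemical
    master equation semantics.  Zero whenever any ``n_i < nu_i``.
    """
    a = float(reaction.rate_constant)
    for i, nu in enumerate(reaction.reactant_counts):
        nu = int(nu)
        if nu == 0:
            continue
        n = int(counts[i])
        if n < nu:
            return 0.0
        if nu == 1:
            a *= n
        else:
            for k in range(nu):
                a *= (n - k)
            a /= math.factorial(nu)
    return a


def evaluate_propensities(network: ReactionNetwork, state: SystemState | Sequence[int]) -> np.ndarray:
    """Propensity vector ``f_r(n)`` for every reaction at the given state."""
    counts = state.counts if isinstance(state, SystemState) else np.asarray(state, dtype=np.int64)
    out = np.empty(network.n_reactions, dtype=np.float64)
    for j, r in enumerate(network.reactions):
        if r.custom_propensity is not None:
            a = float(r.custom_propensity(counts))
            if not math.isfinite(a) or a < 0:
                label = r.name or f"reaction[{j}]"
                raise PropensityError(f"custom propensity of {label} returned {a!r}")
            out[j] = a
        else:
            out[j] = mass_action_propensity(r, counts)
    return out


def apply_change(counts: Sequence[int], delta: Sequence[int]):
    """Elementwise state update; reports (does not clamp) negative results.

    Returns ``(new_counts, deficit_indices)`` where ``deficit_indices``
    lists species driven below zero.  Callers in the delay engines use the
    deficit report to trigger pending-event conflict resolution rather
    than treating it as an immediate error.
    """
    new = np.asarray(counts, dtype=np.int64) + np.asarray(delta, dtype=np.int64)
    deficit = np.flatnonzero(new < 0)
    return new, deficit


def compile_propensity_evaluator(network: ReactionNetwork):
    """Return a fast closure ``eval(counts, out)`` filling the propensity vector.

    Counts may be any indexable integer sequence (the engines keep a plain
    Python list in their hot loop).  Mass-action terms are unrolled into
    (species, order) pairs at compile time.
    """
    mass: list[tuple[int, float, tuple[tuple[int, int], ...]]] = []
    custom: list[tuple[int, Callable, str]] = []
    for j, r in enumerate(network.reactions):
        if r.custom_propensity is not None:
            custom.append((j, r.custom_propensity, r.name or f"reaction[{j}]"))
        else:
            pairs = tuple((i, int(nu)) for i, nu in enumerate(r.reactant_counts) if nu > 0)
            mass.append((j, float(r.rate_constant), pairs))
    inf = math.inf

    def evaluate(counts, out) -> None:
        for j, c, pairs in mass:
            a = c
            for i, nu in pairs:
                n = counts[i]
                if n < nu:
                    a = 0.0
                    break
                if nu == 1:
                    a *= n
                elif nu == 2:
                    a *= n * (n - 1) * 0.5
                else:
                    f = 1.0
                    for k in range(nu):
                        f *= (n - k)
                    a *= f / math.factorial(nu)
            out[j] = a
        for j, fn, label in custom:
            a = fn(counts)
            if a < 0 or a != a or a == inf:
                raise PropensityError(f"custom propensity of {label} returned {a!r}")
            out[j] = a

    return evaluate
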