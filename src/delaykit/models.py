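"""Built-in model constructors.

Four worked systems ship with the package:

* ``bursty_model`` — bursty transcription of nascent mRNA with a fixed
  molecule lifetime (delayed degradation),
* ``refractory_model`` — a three-state promoter cycle producing mRNA only
  in the active state, again with delayed mRNA removal,
* ``rna_velocity_model`` — the two-phase unspliced/spliced mRNA kinetics
  behind RNA-velocity analysis of single-cell data,
* ``ast_model`` — the lung-cancer adeno-to-squamous transition (AST)
  circuit of FOXA2/NKX2-1 versus P63/SOX2, converted from its published
  concentration-based ODEs to molecule counts, optionally with a SOX2
  degrader modelled as a delayed degradation reaction.

A generic two-gene toggle switch is included as a small bistable test
system.  ``convert_concentration_model`` performs the general
concentration-to-molecule rescaling ``X = x * V * N_A``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Callable, Optional, Sequence

import numpy as np

from .engines.base import Ensemble, SimulationRequest, Trajectory
from .engines.delayed import PendingEventQueue, _CORES, _Compiled
from .network import (
    DelaySpec,
    Reaction,
    ReactionNetwork,
    SpeciesSet,
    build_network,
    make_reaction,
)

__all__ = [
    "AVOGADRO",
    "ConversionContext",
    "convert_concentration_model",
    "bursty_model",
    "bursty_burst_propensities",
    "refractory_model",
    "refractory_active_fraction",
    "RnaVelocityModel",
    "rna_velocity_model",
    "simulate_rna_velocity",
    "ASTParameters",
    "ast_model",
    "ast_ode_rhs",
    "ast_concentration_rhs",
    "toggle_switch_model",
]

#: Avogadro constant as used throughout (molecules per mole).
AVOGADRO = 6.023e23


@dataclass(frozen=True)
class ConversionContext:
    """Volume context for converting concentrations to molecule counts.

    ``B = volume * avogadro`` is the number of molecules corresponding to
    one concentration unit; a system volume of 1e-20 L gives B = 6023.
    """

    volume: float
    avogadro: float = AVOGADRO

    def __post_init__(self) -> None:
        if self.volume <= 0:
            raise ValueError("volume must be positive")

    @property
    def B(self) -> float:
        return self.volume * self.avogadro


def convert_concentration_model(
    rhs: Callable[[float, np.ndarray], np.ndarray],
    context: ConversionContext | float,
) -> Callable[[float, np.ndarray], np.ndarray]:
    """Rescale a concentration-based ODE right-hand side to molecule counts.

    Given ``dx/dt = f(t, x)`` in concentration units, the molecule-count
    system ``X = B x`` obeys ``dX/dt = B f(t, X / B)``.  With ``B = 1``
    this is the identity.
    """
    B = context.B if isinstance(context, ConversionContext) else float(context)
    if B <= 0:
        raise ValueError("scaling factor B must be positive")

    def molecule_rhs(t: float, X: np.ndarray) -> np.ndarray:
        return B * np.asarray(rhs(t, np.asarray(X, dtype=float) / B))

    return molecule_rhs


# ---------------------------------------------------------------------------
# Bursty model
# ---------------------------------------------------------------------------

def bursty_burst_propensities(alpha: float, b: float, tail_mass: float = 1e-6) -> np.ndarray:
    """Propensities of bursts of size k = 1..k_max.

    Burst sizes are geometric with mean ``b`` (on k >= 0; conditioned on a
    visible burst k >= 1): the channel producing ``k`` molecules has
    constant propensity ``alpha * b**k / (1+b)**(k+1)``.  The family is
    truncated where the relative residual tail drops below ``tail_mass``;
    the truncated total equals ``alpha * b / (1+b)`` up to that tail.
    """
    if alpha <= 0 or b <= 0:
        raise ValueError("alpha and b must be positive")
    r = b / (1.0 + b)
    k_max = 1
    while r ** (k_max + 1) >= tail_mass:
        k_max += 1
    k = np.arange(1, k_max + 1)
    return alpha * b ** k / (1.0 + b) ** (k + 1)


def bursty_model(alpha: float = 0.0282, b: float = 3.46, tau: float = 120.0,
                 tail_mass: float = 1e-6) -> ReactionNetwork:
    """Bursty transcription with delayed degradation.

    Nascent mRNA is produced in geometric bursts (frequency ``alpha``,
    mean size ``b``); every molecule is removed exactly ``tau`` time units
    after its creation.  A burst of size ``k`` therefore adds ``k``
    molecules immediately and schedules their joint removal at ``t+tau``.
    Stationary mean is ``alpha * b * tau`` (Little's law).
    """
    if tau < 0:
        raise ValueError("tau must be >= 0")
    props = bursty_burst_propensities(alpha, b, tail_mass)
    species = SpeciesSet(("M",))
    reactions = []
    for k, p in enumerate(props, start=1):
        reactions.append(Reaction(
            reactant_counts=np.zeros(1, dtype=np.int64),
            s_column=np.array([k], dtype=np.int64),
            s_delay_column=np.array([-k], dtype=np.int64),
            rate_constant=float(p),
            delay=DelaySpec.consuming(tau),
            name=f"burst_{k}",
        ))
    return build_network(species, reactions)


# ---------------------------------------------------------------------------
# Refractory model
# ---------------------------------------------------------------------------

def refractory_model(k1: float = 0.15, k2: float = 0.1, k3: float = 0.05,
                     k4: float = 10.0, tau: float = 1.0) -> ReactionNetwork:
    """Three-state promoter cycle G0 -> G1 -> G2 -> G0 with delayed mRNA removal.

    mRNA is produced only in the active state G2 (rate ``k4``) and each
    molecule is removed ``tau`` after synthesis.  The two silent states
    make the off periods non-exponential, producing the characteristic
    bimodal mRNA distribution with a heavy mode at zero.
    """
    if min(k1, k2, k3) <= 0 or k4 < 0 or tau < 0:
        raise ValueError("switching rates must be > 0, k4 and tau >= 0")
    species = SpeciesSet(("G0", "G1", "G2", "M"))
    z = lambda: np.zeros(4, dtype=np.int64)

    def vec(**kw):
        v = z()
        for nm, c in kw.items():
            v[species.index(nm)] = c
        return v

    reactions = [
        make_reaction(species, {"G0": 1}, {"G1": 1}, rate=k1, name="G0->G1"),
        make_reaction(species, {"G1": 1}, {"G2": 1}, rate=k2, name="G1->G2"),
        make_reaction(species, {"G2": 1}, {"G0": 1}, rate=k3, name="G2->G0"),
        # transcription: M appears now, disappears tau later; G2 is catalytic
        Reaction(reactant_counts=vec(G2=1), s_column=vec(M=1), s_delay_column=vec(M=-1),
                 rate_constant=k4, delay=DelaySpec.consuming(tau), name="transcribe"),
    ]
    return build_network(species, reactions)


def refractory_active_fraction(k1: float, k2: float, k3: float) -> float:
    """Stationary probability of the transcribing state G2 of the cycle.

    The cycle is a renewal process; occupancy is proportional to the mean
    dwell time 1/k of each state.
    """
    w = (1.0 / k1, 1.0 / k2, 1.0 / k3)
    return w[2] / sum(w)


# ---------------------------------------------------------------------------
# RNA velocity model
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RnaVelocityModel:
    """Two-phase unspliced (U) / spliced (S) mRNA kinetics.

    Phase 1 (up-regulation): transcription at rate ``alpha``, splicing
    U -> S at ``beta``, degradation of S at ``gamma``.  At ``t_switch``
    transcription shuts off (``alpha = 0``) and both species decay back to
    zero.  With ``tau`` set, S degradation is a completion-only delayed
    reaction; scheduled removals survive the switch.
    """

    alpha: float = 20.0
    beta: float = 1.0
    gamma: float = 0.5
    t_switch: float = 50.0
    tau: float | None = None

    def __post_init__(self) -> None:
        if min(self.alpha, self.beta, self.gamma) < 0:
            raise ValueError("rates must be >= 0")
        if self.t_switch <= 0:
            raise ValueError("t_switch must be > 0")

    def network(self, phase: int) -> ReactionNetwork:
        """Reaction network of phase 1 (production on) or phase 2 (off)."""
        if phase not in (1, 2):
            raise ValueError("phase must be 1 or 2")
        species = SpeciesSet(("U", "S"))
        alpha = self.alpha if phase == 1 else 0.0
        if self.tau is None:
            deg = make_reaction(species, {"S": 1}, {}, rate=self.gamma, name="degrade")
        else:
            deg = make_reaction(species, {"S": 1}, {}, rate=self.gamma,
                                delay=DelaySpec.completion_only(self.tau), name="degrade")
        return build_network(species, [
            make_reaction(species, {}, {"U": 1}, rate=alpha, name="transcribe"),
            make_reaction(species, {"U": 1}, {"S": 1}, rate=self.beta, name="splice"),
            deg,
        ])


def rna_velocity_model(alpha: float = 20.0, beta: float = 1.0, gamma: float = 0.5,
                       t_switch: float = 50.0, tau: float | None = None) -> RnaVelocityModel:
    return RnaVelocityModel(alpha, beta, gamma, t_switch, tau)


def simulate_rna_velocity(
    model: RnaVelocityModel,
    t_final: float,
    output_times: Sequence[float],
    n_samples: int,
    seed: int = 0,
    engine: str = "delay_rejection",
) -> Ensemble:
    """Simulate the two-phase process, carrying state *and* the pending
    delayed-removal queue across the transcription shut-off."""
    if t_final <= model.t_switch:
        raise ValueError("t_final must exceed t_switch")
    core = _CORES[engine]
    grid = np.asarray(output_times, dtype=np.float64)
    comp1 = _Compiled(model.network(1))
    comp2 = _Compiled(model.network(2))
    states = np.empty((n_samples, len(grid), 2), dtype=np.int64)
    for i in range(n_samples):
        rng = np.random.default_rng(int(seed) + i)
        counts = [0, 0]
        queue = PendingEventQueue()
        row = states[i]
        counts, t, gi = core(comp1, counts, 0.0, model.t_switch, grid, row, 0, queue, rng)
        core(comp2, counts, model.t_switch, float(t_final), grid, row, gi, queue, rng)
    return Ensemble(times=grid, states=states, species=("U", "S"))


# ---------------------------------------------------------------------------
# AST (adeno-to-squamous transition) network
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ASTParameters:
    """Published parameter set of the AST circuit; ``alpha_S`` is the
    control parameter tuning SOX2 basal production."""

    alpha_F: float = 2.9
    alpha_N: float = 1.0
    alpha_P: float = 1.0
    beta_S: float = 1.3
    alpha_S: float = 0.05
    a1: float = 1.0
    a2: float = 1.0
    a3: float = 0.8
    a4: float = 2.0
    a5: float = 0.8
    a6: float = 1.0
    a7: float = 2.0
    a8: float = 1.0
    a9: float = 1.0
    d_F: float = 1.0
    d_N: float = 1.0
    d_P: float = 1.0
    d_S: float = 0.4

    def with_alpha_s(self, alpha_S: float) -> "ASTParameters":
        return replace(self, alpha_S=alpha_S)


def ast_concentration_rhs(params: ASTParameters) -> Callable[[float, np.ndarray], np.ndarray]:
    """Concentration-based ODEs of the AST circuit (F, N, P, S order)."""
    p = params

    def rhs(t: float, x: np.ndarray) -> np.ndarray:
        F, N, P, S = x
        dF = p.alpha_F / (1 + p.a1 * P * P + p.a2 * S * S) - p.d_F * F
        dN = p.alpha_N * (1 + F * F) / (1 + p.a3 * F * F + p.a4 * S * S) - p.d_N * N
        dP = p.alpha_P * (1 + S * S) / (1 + p.a5 * S * S + p.a6 * N * N) - p.d_P * P
        dS = (p.beta_S * S * S / (p.a7 ** 2 + S * S)
              + p.alpha_S / (1 + p.a8 * F * F + p.a9 * N * N) - p.d_S * S)
        return np.array([dF, dN, dP, dS])

    return rhs


def ast_ode_rhs(params: ASTParameters, B: float = 6023.0):
    """Molecule-based AST ODEs: the concentration system rescaled by B."""
    return convert_concentration_model(ast_concentration_rhs(params), B)


def _ast_production_propensities(p: ASTParameters, B: float):
    """The four Hill-type production propensities in molecule units."""
    B2 = B * B
    B3 = B2 * B
    a7B2 = (p.a7 * B) ** 2

    def prod_F(n):
        P, S = n[2], n[3]
        return B3 * p.alpha_F / (B2 + p.a1 * P * P + p.a2 * S * S)

    def prod_N(n):
        F, S = n[0], n[3]
        return B * p.alpha_N * (B2 + F * F) / (B2 + p.a3 * F * F + p.a4 * S * S)

    def prod_P(n):
        N, S = n[1], n[3]
        return B * p.alpha_P * (B2 + S * S) / (B2 + p.a5 * S * S + p.a6 * N * N)

    def prod_S(n):
        F, N, S = n[0], n[1], n[3]
        return (B * p.beta_S * S * S / (a7B2 + S * S)
                + B3 * p.alpha_S / (B2 + p.a8 * F * F + p.a9 * N * N))

    return prod_F, prod_N, prod_P, prod_S


def ast_model(
    params: ASTParameters | None = None,
    B: float = 6023.0,
    degrader: Optional[dict] = None,
) -> ReactionNetwork:
    """Molecule-based AST network as a reaction system.

    One production channel (custom Hill-type propensity, the positive term
    of each molecule-based ODE) and one linear degradation channel per
    species.  ``degrader={'k_deg': ..., 'tau_S': ...}`` adds the SOX2
    degrader: an extra channel with propensity ``k_deg * S`` whose removal
    of one S molecule completes a fixed ``tau_S`` after initiation
    (completion-only, so S is untouched during the lag).
    """
    p = params or ASTParameters()
    if B <= 0:
        raise ValueError("B must be positive")
    species = SpeciesSet(("F", "N", "P", "S"))
    prod_F, prod_N, prod_P, prod_S = _ast_production_propensities(p, B)
    reactions = [
        make_reaction(species, {}, {"F": 1}, propensity=prod_F, name="produce_F"),
        make_reaction(species, {"F": 1}, {}, rate=p.d_F, name="degrade_F"),
        make_reaction(species, {}, {"N": 1}, propensity=prod_N, name="produce_N"),
        make_reaction(species, {"N": 1}, {}, rate=p.d_N, name="degrade_N"),
        make_reaction(species, {}, {"P": 1}, propensity=prod_P, name="produce_P"),
        make_reaction(species, {"P": 1}, {}, rate=p.d_P, name="degrade_P"),
        make_reaction(species, {}, {"S": 1}, propensity=prod_S, name="produce_S"),
        make_reaction(species, {"S": 1}, {}, rate=p.d_S, name="degrade_S"),
    ]
    if degrader is not None:
        k_deg = float(degrader["k_deg"])
        tau_S = float(degrader.get("tau_S", 1.0))
        if k_deg < 0:
            raise ValueError("k_deg must be >= 0")
        reactions.append(make_reaction(
            species, {"S": 1}, {}, rate=k_deg,
            delay=DelaySpec.completion_only(tau_S), name="degrader_S"))
    return build_network(species, reactions)


# ---------------------------------------------------------------------------
# Toggle switch (generic bistable test system)
# ---------------------------------------------------------------------------

def toggle_switch_model(alpha: float = 50.0, K: float = 20.0, n_hill: float = 2.0,
                        d: float = 1.0, tau: float | None = None) -> ReactionNetwork:
    """Generic two-gene mutual-repression toggle switch (test system).

    Each gene produces its protein at ``alpha / (1 + (other/K)**n_hill)``
    and degrades linearly at rate ``d`` (optionally with a fixed delay).
    """
    if min(alpha, K, n_hill, d) <= 0:
        raise ValueError("all parameters must be positive")
    species = SpeciesSet(("U", "V"))

    def prod_u(n):
        return alpha / (1.0 + (n[1] / K) ** n_hill)

    def prod_v(n):
        return alpha / (1.0 + (n[0] / K) ** n_hill)

    delay = DelaySpec.completion_only(tau) if tau is not None else None
    reactions = [
        make_reaction(species, {}, {"U": 1}, propensity=prod_u, name="produce_U"),
        make_reaction(species, {"U": 1}, {}, rate=d, delay=delay, name="degrade_U"),
        make_reaction(species, {}, {"V": 1}, propensity=prod_v, name="produce_V"),
        make_reaction(species, {"V": 1}, {}, rate=d, delay=delay, name="degrade_V"),
    ]
    return build_network(species, reactions)
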