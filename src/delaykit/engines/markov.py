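"""The three exact Markovian (non-delay) SSA variants.

All three sample the same continuous-time Markov jump process and are
distributionally interchangeable; they differ only in how the next event
is generated:

* Direct: one Exp(a0) waiting time plus a categorical reaction draw.
* First Reaction: an independent Exp(a_r) candidate time per reaction,
  earliest wins.
* Modified Next Reaction (Anderson): per-reaction unit-rate internal
  clocks ``T_k`` with thresholds ``P_k``; the physical waiting time of
  channel ``k`` is ``(P_k - T_k)/a_k``.
"""

from __future__ import annotations

import numpy as np

from ..network import compile_propensity_evaluator
from .base import SimulationRequest, Trajectory, fill_grid

__all__ = ["simulate_direct", "simulate_first_reaction", "simulate_mnr"]


def _check_markovian(req: SimulationRequest) -> None:
    if req.network.has_delays:
        raise ValueError(
            "network contains delayed reactions; use one of the delay engines "
            "(delay_rejection, delay_direct, delay_mnr)")


def _prepare(req: SimulationRequest):
    _check_markovian(req)
    net = req.network
    evaluate = compile_propensity_evaluator(net)
    s_pairs = [tuple((i, int(d)) for i, d in enumerate(r.s_column) if d != 0)
               for r in net.reactions]
    counts = [int(c) for c in req.initial_counts]
    grid = req.output_times
    states = np.empty((len(grid), net.n_species), dtype=np.int64)
    a = np.empty(net.n_reactions, dtype=np.float64)
    return net, evaluate, s_pairs, counts, grid, states, a


def _apply(counts, pairs) -> None:
    for i, d in pairs:
        v = counts[i] + d
        if v < 0:
            raise ValueError(
                f"state update drove species index {i} negative; "
                "custom propensities must vanish when reactants are exhausted")
        counts[i] = v


def _finish(states, grid, gi, counts, species) -> Trajectory:
    fill_grid(states, grid, gi, np.inf, counts)
    return Trajectory(times=grid, states=states, species=species)


def simulate_direct(req: SimulationRequest) -> Trajectory:
    """Gillespie's Direct method."""
    net, evaluate, s_pairs, counts, grid, states, a = _prepare(req)
    rng = req.rng()
    t, gi, t_final = 0.0, 0, float(req.t_final)
    while True:
        evaluate(counts, a)
        a0 = float(a.sum())
        if a0 <= 0.0:
            break  # exhausted system: state frozen to t_final
        t_next = t + rng.standard_exponential() / a0
        if t_next > t_final:
            break
        gi = fill_grid(states, grid, gi, t_next, counts)
        u = rng.random() * a0
        acc, j = 0.0, 0
        for j in range(len(a)):
            acc += a[j]
            if u < acc:
                break
        _apply(counts, s_pairs[j])
        t = t_next
    return _finish(states, grid, gi, counts, net.species.names)


def simulate_first_reaction(req: SimulationRequest) -> Trajectory:
    """Gillespie's First Reaction method."""
    net, evaluate, s_pairs, counts, grid, states, a = _prepare(req)
    rng = req.rng()
    t, gi, t_final = 0.0, 0, float(req.t_final)
    n_r = net.n_reactions
    while True:
        evaluate(counts, a)
        if not a.any():
            break
        with np.errstate(divide="ignore"):
            taus = rng.standard_exponential(n_r) / a
        j = int(np.argmin(taus))
        t_next = t + float(taus[j])
        if t_next > t_final:
            break
        gi = fill_grid(states, grid, gi, t_next, counts)
        _apply(counts, s_pairs[j])
        t = t_next
    return _finish(states, grid, gi, counts, net.species.names)


def simulate_mnr(req: SimulationRequest) -> Trajectory:
    """Anderson's Modified Next Reaction method.

    Each channel carries an internal (unit-rate Poisson) clock ``T_k`` and
    a next-firing threshold ``P_k``; the channel whose physical gap
    ``(P_k - T_k)/a_k`` is smallest fires next.
    """
    net, evaluate, s_pairs, counts, grid, states, a = _prepare(req)
    rng = req.rng()
    t, gi, t_final = 0.0, 0, float(req.t_final)
    n_r = net.n_reactions
    T = np.zeros(n_r)
    P = rng.standard_exponential(n_r)
    while True:
        evaluate(counts, a)
        with np.errstate(divide="ignore", invalid="ignore"):
            gaps = np.where(a > 0.0, (P - T) / a, np.inf)
        j = int(np.argmin(gaps))
        dt = float(gaps[j])
        if not np.isfinite(dt) or t + dt > t_final:
            break
        t += dt
        gi = fill_grid(states, grid, gi, t, counts)
        T += a * dt
        P[j] += rng.standard_exponential()
        _apply(counts, s_pairs[j])
    return _finish(states, grid, gi, counts, net.species.names)
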