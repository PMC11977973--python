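"""Exact delay-capable engines and the pending-completion machinery.

A delayed firing schedules a *pending event*: a per-species delta to be
applied at ``t + tau``.  The time-ordered queue of pending events is the
non-Markovian memory of the process.  All three engines interleave
scheduled completions with freshly sampled firings; when a completion
time coincides exactly with a sampled firing time, the completion is
applied first (completions were committed in the past, and the fixed
order keeps runs reproducible).

Conflict resolution
-------------------
A completion may propose removing molecules that a non-delayed channel
already consumed.  When a state update would drive a species negative,
one pending event that decrements that species is cancelled, chosen
uniformly at random; the cancelled event's scheduled decrement (capped
at the deficit) is credited to the proposal, and the check repeats until
the proposal is feasible.  If the infeasible proposal is itself a
completion and no cancellable pending event exists, the proposal's own
deficit is dropped (an orphaned completion whose target molecules are
already gone); an immediate (non-delayed) proposal with no cancellable
event is a hard model-consistency error.
"""

from __future__ import annotations

import heapq
import math
from typing import Optional, Sequence

import numpy as np

from ..network import DelayKind, ReactionNetwork, compile_propensity_evaluator
from .base import SimulationRequest, Trajectory, fill_grid

__all__ = [
    "PendingEvent",
    "PendingEventQueue",
    "schedule_completion",
    "resolve_conflict",
    "ConflictResolutionError",
    "simulate_delay_rejection",
    "simulate_delay_direct",
    "simulate_delay_mnr",
]


class ConflictResolutionError(RuntimeError):
    """No pending event can be cancelled to make an immediate update feasible."""


class PendingEvent:
    """A scheduled delayed completion: apply ``pairs`` at ``completion_time``.

    ``active`` is cleared when the event either executes (popped) or is
    cancelled by conflict resolution; inactive events are skipped lazily
    everywhere.
    """

    __slots__ = ("completion_time", "reaction_index", "pairs", "active")

    def __init__(self, completion_time: float, reaction_index: int,
                 pairs: Sequence[tuple[int, int]]):
        if not math.isfinite(completion_time):
            raise ValueError("completion_time must be finite")
        self.completion_time = float(completion_time)
        self.reaction_index = int(reaction_index)
        self.pairs = tuple(pairs)  # sparse (species_index, delta) with delta != 0
        self.active = True

    @property
    def cancelled(self) -> bool:
        return not self.active

    @property
    def delta(self) -> dict[int, int]:
        return dict(self.pairs)

    def decrements(self, species_index: int) -> int:
        for i, d in self.pairs:
            if i == species_index and d < 0:
                return -d
        return 0

    def __repr__(self) -> str:  # pragma: no cover
        return f"PendingEvent(t={self.completion_time}, r={self.reaction_index}, {dict(self.pairs)})"


class PendingEventQueue:
    """Min-heap of pending completions ordered by completion time.

    Ties are broken by insertion order (FIFO).  Cancellation is lazy: a
    cancelled event stays in the heap but is skipped on pop/peek.
    """

    def __init__(self) -> None:
        self._heap: list[tuple[float, int, PendingEvent]] = []
        self._seq = 0
        self._live = 0
        # per-species lists of events that decrement that species, for
        # O(1)-amortized uniform candidate sampling in conflict resolution
        self._dec_index: dict[int, list[PendingEvent]] = {}

    def __len__(self) -> int:
        return self._live

    def push(self, event: PendingEvent) -> None:
        heapq.heappush(self._heap, (event.completion_time, self._seq, event))
        self._seq += 1
        self._live += 1
        for i, d in event.pairs:
            if d < 0:
                self._dec_index.setdefault(i, []).append(event)

    def _skip_inactive(self) -> None:
        while self._heap and not self._heap[0][2].active:
            heapq.heappop(self._heap)

    def peek(self) -> Optional[PendingEvent]:
        self._skip_inactive()
        return self._heap[0][2] if self._heap else None

    def pop(self) -> PendingEvent:
        self._skip_inactive()
        if not self._heap:
            raise IndexError("pop from an empty pending-event queue")
        ev = heapq.heappop(self._heap)[2]
        ev.active = False  # executed; no longer cancellable
        self._live -= 1
        return ev

    def cancel(self, event: PendingEvent) -> None:
        if event.active:
            event.active = False
            self._live -= 1

    def sample_decrement(self, species_index: int,
                         rng: np.random.Generator) -> Optional[PendingEvent]:
        """Uniformly sample a live pending event decrementing the species.

        Stale (inactive) entries found along the way are swap-deleted, so
        repeated sampling stays O(1) amortized even on large queues.
        """
        lst = self._dec_index.get(species_index)
        while lst:
            k = int(rng.integers(len(lst))) if len(lst) > 1 else 0
            ev = lst[k]
            if ev.active:
                return ev
            lst[k] = lst[-1]
            lst.pop()
        return None

    def live_events(self) -> list[PendingEvent]:
        return [e for _, _, e in self._heap if e.active]

    def copy(self) -> "PendingEventQueue":
        q = PendingEventQueue()
        for _, _, e in sorted(self._heap, key=lambda x: (x[0], x[1])):
            if e.active:
                q.push(PendingEvent(e.completion_time, e.reaction_index, e.pairs))
        return q


def schedule_completion(queue: PendingEventQueue, event: PendingEvent) -> PendingEventQueue:
    """Insert a pending completion, preserving the queue ordering invariant."""
    queue.push(event)
    return queue


def resolve_conflict(
    queue: PendingEventQueue,
    counts,
    rng: np.random.Generator,
    proposal_is_completion: bool = False,
):
    """Restore feasibility of an already-applied update that went negative.

    ``counts`` (mutable sequence, possibly containing negative entries
    from the proposal) is repaired in place.  Returns the list of
    cancelled events.  See the module docstring for the rule.
    """
    removed: list[PendingEvent] = []
    while True:
        deficit = [i for i, v in enumerate(counts) if v < 0]
        if not deficit:
            return removed
        ev = queue.sample_decrement(deficit[0], rng)
        if ev is None:
            if proposal_is_completion:
                # Orphaned completion: its target molecules were already
                # removed by another channel.  Drop the residual deficit.
                counts[deficit[0]] = 0
                continue
            raise ConflictResolutionError(
                f"species index {deficit[0]} driven negative with no pending "
                "delayed event available to cancel")
        queue.cancel(ev)
        removed.append(ev)
        dset = set(deficit)
        for i, d in ev.pairs:
            if d < 0 and i in dset and counts[i] < 0:
                # cancelled decrement credited, capped at the deficit
                counts[i] = min(counts[i] - d, 0)


# ---------------------------------------------------------------------------
# engine cores
# ---------------------------------------------------------------------------

_NONE, _CONSUMING, _COMPLETION_ONLY = 0, 1, 2


class _Compiled:
    """Per-network precomputation shared by the three delay engines."""

    __slots__ = ("evaluate", "s_pairs", "sdelay_pairs", "full_pairs", "kinds",
                 "delays", "n_species", "n_reactions", "species")

    def __init__(self, net: ReactionNetwork):
        self.evaluate = compile_propensity_evaluator(net)
        self.n_species = net.n_species
        self.n_reactions = net.n_reactions
        self.species = net.species.names
        self.s_pairs, self.sdelay_pairs, self.full_pairs = [], [], []
        self.kinds, self.delays = [], []
        for r in net.reactions:
            sp = tuple((i, int(d)) for i, d in enumerate(r.s_column) if d != 0)
            dp = tuple((i, int(d)) for i, d in enumerate(r.s_delay_column) if d != 0)
            full = {}
            for i, d in list(sp) + list(dp):
                full[i] = full.get(i, 0) + d
            self.s_pairs.append(sp)
            self.sdelay_pairs.append(dp)
            self.full_pairs.append(tuple((i, d) for i, d in full.items() if d != 0))
            self.kinds.append({DelayKind.NONE: _NONE, DelayKind.CONSUMING: _CONSUMING,
                               DelayKind.COMPLETION_ONLY: _COMPLETION_ONLY}[r.delay.kind])
            self.delays.append(r.delay)


def _apply_pairs(counts, pairs, queue, rng, is_completion: bool) -> None:
    deficit = False
    for i, d in pairs:
        v = counts[i] + d
        counts[i] = v
        if v < 0:
            deficit = True
    if deficit:
        resolve_conflict(queue, counts, rng, proposal_is_completion=is_completion)


def _fire(j: int, t: float, counts, queue: PendingEventQueue, comp: _Compiled,
          rng: np.random.Generator) -> None:
    kind = comp.kinds[j]
    if kind == _NONE:
        _apply_pairs(counts, comp.s_pairs[j], queue, rng, False)
        return
    tau = comp.delays[j].draw(rng)
    if kind == _CONSUMING:
        _apply_pairs(counts, comp.s_pairs[j], queue, rng, False)
        pairs = comp.sdelay_pairs[j]
    else:  # completion_only: all change deferred
        pairs = comp.full_pairs[j]
    if not pairs:
        return
    if tau <= 0.0:
        _apply_pairs(counts, pairs, queue, rng, True)
    else:
        queue.push(PendingEvent(t + tau, j, pairs))


def _pop_completion(t: float, counts, queue, comp, rng) -> None:
    ev = queue.pop()
    _apply_pairs(counts, ev.pairs, queue, rng, True)


def _final_fill(states, grid, gi: int, t_final: float, counts) -> int:
    n = len(grid)
    while gi < n and grid[gi] <= t_final:
        states[gi] = counts
        gi += 1
    return gi


def advance_delay_rejection(comp: _Compiled, counts, t: float, t_final: float,
                            grid, states, gi: int, queue: PendingEventQueue,
                            rng: np.random.Generator):
    """Rejection method: a tentative Exp(a0) step is discarded whenever a
    scheduled completion intervenes; time then advances to that completion."""
    a = np.empty(comp.n_reactions)
    while True:
        comp.evaluate(counts, a)
        a0 = float(a.sum())
        head = queue.peek()
        if a0 <= 0.0:
            if head is None or head.completion_time > t_final:
                t = t_final
                break
            gi = fill_grid(states, grid, gi, head.completion_time, counts)
            t = head.completion_time
            _pop_completion(t, counts, queue, comp, rng)
            continue
        dt = rng.standard_exponential() / a0
        if head is not None and head.completion_time <= t + dt:
            if head.completion_time > t_final:
                t = t_final
                break
            gi = fill_grid(states, grid, gi, head.completion_time, counts)
            t = head.completion_time  # reject the tentative step
            _pop_completion(t, counts, queue, comp, rng)
            continue
        if t + dt > t_final:
            t = t_final
            break
        t += dt
        gi = fill_grid(states, grid, gi, t, counts)
        u = rng.random() * a0
        acc = 0.0
        for j in range(comp.n_reactions):
            acc += a[j]
            if u < acc:
                break
        _fire(j, t, counts, queue, comp, rng)
    gi = _final_fill(states, grid, gi, t_final, counts)
    return counts, t, gi


def advance_delay_direct(comp: _Compiled, counts, t: float, t_final: float,
                         grid, states, gi: int, queue: PendingEventQueue,
                         rng: np.random.Generator):
    """Direct method for delays: the waiting time solves
    ``integral of a0 over (t, t+w] = Exp(1)`` with ``a0`` piecewise constant
    across scheduled completions (propensities re-evaluated after each)."""
    a = np.empty(comp.n_reactions)
    while t < t_final:
        comp.evaluate(counts, a)
        a0 = float(a.sum())
        rem = rng.standard_exponential()
        t_fire = None
        while True:
            head = queue.peek()
            if a0 <= 0.0:
                if head is None or head.completion_time > t_final:
                    t = t_final
                    break
                gi = fill_grid(states, grid, gi, head.completion_time, counts)
                t = head.completion_time
                _pop_completion(t, counts, queue, comp, rng)
                comp.evaluate(counts, a)
                a0 = float(a.sum())
                continue
            if head is not None and head.completion_time <= t_final and \
                    a0 * (head.completion_time - t) <= rem:
                rem -= a0 * (head.completion_time - t)
                gi = fill_grid(states, grid, gi, head.completion_time, counts)
                t = head.completion_time
                _pop_completion(t, counts, queue, comp, rng)
                comp.evaluate(counts, a)
                a0 = float(a.sum())
                continue
            t_fire = t + rem / a0
            break
        if t_fire is None:
            break
        if t_fire > t_final:
            t = t_final
            break
        t = t_fire
        gi = fill_grid(states, grid, gi, t, counts)
        u = rng.random() * a0
        acc = 0.0
        for j in range(comp.n_reactions):
            acc += a[j]
            if u < acc:
                break
        _fire(j, t, counts, queue, comp, rng)
    gi = _final_fill(states, grid, gi, t_final, counts)
    return counts, t, gi


def advance_delay_mnr(comp: _Compiled, counts, t: float, t_final: float,
                      grid, states, gi: int, queue: PendingEventQueue,
                      rng: np.random.Generator):
    """Anderson's modified next reaction method with a completion queue:
    the next event is the earlier of the earliest channel firing and the
    earliest scheduled completion."""
    n_r = comp.n_reactions
    a = np.empty(n_r)
    T = np.zeros(n_r)
    P = rng.standard_exponential(n_r)
    while True:
        comp.evaluate(counts, a)
        with np.errstate(divide="ignore", invalid="ignore"):
            gaps = np.where(a > 0.0, (P - T) / a, np.inf)
        j = int(np.argmin(gaps))
        dt = float(gaps[j])
        head = queue.peek()
        t_fire = t + dt if math.isfinite(dt) else math.inf
        if head is not None and head.completion_time <= t_fire:
            if head.completion_time > t_final:
                t = t_final
                break
            delt = head.completion_time - t
            T += a * delt
            gi = fill_grid(states, grid, gi, head.completion_time, counts)
            t = head.completion_time
            _pop_completion(t, counts, queue, comp, rng)
            continue
        if t_fire > t_final:
            t = t_final
            break
        T += a * dt
        t = t_fire
        gi = fill_grid(states, grid, gi, t, counts)
        P[j] += rng.standard_exponential()
        _fire(j, t, counts, queue, comp, rng)
    gi = _final_fill(states, grid, gi, t_final, counts)
    return counts, t, gi


_CORES = {
    "delay_rejection": advance_delay_rejection,
    "delay_direct": advance_delay_direct,
    "delay_mnr": advance_delay_mnr,
}


def _simulate(req: SimulationRequest, core) -> Trajectory:
    comp = _Compiled(req.network)
    counts = [int(c) for c in req.initial_counts]
    grid = req.output_times
    states = np.empty((len(grid), comp.n_species), dtype=np.int64)
    queue = PendingEventQueue()
    rng = req.rng()
    core(comp, counts, 0.0, float(req.t_final), grid, states, 0, queue, rng)
    return Trajectory(times=grid, states=states, species=comp.species)


def simulate_delay_rejection(req: SimulationRequest) -> Trajectory:
    return _simulate(req, advance_delay_rejection)


def simulate_delay_direct(req: SimulationRequest) -> Trajectory:
    return _simulate(req, advance_delay_direct)


def simulate_delay_mnr(req: SimulationRequest) -> Trajectory:
    return _simulate(req, advance_delay_mnr)
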