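import numpy as np
import pytest
from scipy import stats

from delaykit import (
    DelaySpec,
    PendingEvent,
    PendingEventQueue,
    Reaction,
    SimulationRequest,
    SpeciesSet,
    build_network,
    make_reaction,
    resolve_conflict,
    run_ensemble,
    schedule_completion,
    simulate_delay_direct,
    simulate_delay_mnr,
    simulate_delay_rejection,
    simulate_direct,
    simulate_mnr,
)
from delaykit.engines.delayed import ConflictResolutionError
from conftest import delayed_birth_network, zero_delay_birth_death

DELAY_ENGINES = {
    "delay_rejection": simulate_delay_rejection,
    "delay_direct": simulate_delay_direct,
    "delay_mnr": simulate_delay_mnr,
}


class TestPendingEventQueue:
    def test_time_ordering(self):
        q = PendingEventQueue()
        schedule_completion(q, PendingEvent(5.0, 0, ((0, -1),)))
        schedule_completion(q, PendingEvent(3.0, 0, ((0, -1),)))
        assert q.peek().completion_time == 3.0
        assert q.pop().completion_time == 3.0
        assert q.pop().completion_time == 5.0
        assert len(q) == 0

    def test_fifo_tie_break(self):
        q = PendingEventQueue()
        a = PendingEvent(4.0, 0, ((0, -1),))
        b = PendingEvent(4.0, 1, ((0, -1),))
        q.push(a)
        q.push(b)
        assert q.pop() is a
        assert q.pop() is b

    def test_pop_order_nondecreasing_random_times(self):
        rng = np.random.default_rng(0)
        q = PendingEventQueue()
        for t in rng.uniform(0, 100, 200):
            q.push(PendingEvent(float(t), 0, ((0, -1),)))
        times = [q.pop().completion_time for _ in range(200)]
        assert (np.diff(times) >= 0).all()

    def test_cancelled_events_skipped(self):
        q = PendingEventQueue()
        a = PendingEvent(1.0, 0, ((0, -1),))
        b = PendingEvent(2.0, 0, ((0, -1),))
        q.push(a)
        q.push(b)
        q.cancel(a)
        assert len(q) == 1
        assert q.pop() is b


class TestResolveConflict:
    def _queue_with_decrements(self, n, t0=10.0):
        q = PendingEventQueue()
        events = [PendingEvent(t0 + k, 0, ((0, -1),)) for k in range(n)]
        for e in events:
            q.push(e)
        return q, events

    def test_uniform_removal_chi2(self):
        """The cancelled event is chosen uniformly among the conflicting ones."""
        hits = np.zeros(3)
        for trial in range(3000):
            q, events = self._queue_with_decrements(3)
            counts = [-1]  # proposal already applied, drove X to -1
            rng = np.random.default_rng(trial)
            removed = resolve_conflict(q, counts, rng)
            assert len(removed) == 1 and counts[0] == 0 and len(q) == 2
            hits[events.index(removed[0])] += 1
        p = stats.chisquare(hits).pvalue
        assert p > 0.01, f"removal not uniform: {hits}, p={p}"

    def test_no_deficit_is_noop(self):
        q, _ = self._queue_with_decrements(3)
        counts = [2]
        removed = resolve_conflict(q, counts, np.random.default_rng(0))
        assert removed == [] and len(q) == 3 and counts == [2]

    def test_unresolvable_deficit_raises(self):
        q = PendingEventQueue()
        q.push(PendingEvent(5.0, 0, ((1, -1),)))  # decrements a different species
        with pytest.raises(ConflictResolutionError):
            resolve_conflict(q, [-1, 3], np.random.default_rng(0))

    def test_orphaned_completion_dropped(self):
        # a completion whose target molecules are already gone, nothing to cancel
        q = PendingEventQueue()
        counts = [-1]
        removed = resolve_conflict(q, counts, np.random.default_rng(0),
                                   proposal_is_completion=True)
        assert removed == [] and counts == [0]

    def test_multiunit_credit_capped_at_deficit(self):
        q = PendingEventQueue()
        ev = PendingEvent(5.0, 0, ((0, -4),))
        q.push(ev)
        counts = [-1]
        removed = resolve_conflict(q, counts, np.random.default_rng(0))
        assert removed == [ev]
        assert counts == [0]  # capped: cancelling -4 does not mint molecules


@pytest.mark.parametrize("engine", list(DELAY_ENGINES))
class TestDelayEngines:
    def test_seed_determinism(self, mdinf, engine):
        grid = np.linspace(0, 20, 40)
        a = DELAY_ENGINES[engine](SimulationRequest(mdinf, [0], 20.0, grid, seed=9))
        b = DELAY_ENGINES[engine](SimulationRequest(mdinf, [0], 20.0, grid, seed=9))
        assert (a.states == b.states).all()

    def test_mdinf_stationary_poisson(self, mdinf, engine):
        """Deterministic lifetime tau after birth: stationary X ~ Poisson(alpha*tau)."""
        grid = np.arange(0.0, 61.0, 2.0)
        ens = run_ensemble(mdinf, [0], 60.0, grid, 40, seed=17, engine=engine)
        pooled = ens.pooled(np.arange(10.0, 61.0, 2.0)).ravel()
        assert pooled.mean() == pytest.approx(10.0, abs=0.5)
        assert pooled.var(ddof=1) / pooled.mean() == pytest.approx(1.0, abs=0.15)

    def test_zero_delay_reduction(self, engine):
        """With all delays zero the delay engines sample the Markovian law."""
        net = zero_delay_birth_death()
        grid = np.array([0.0, 8.0])
        n = 1200
        delayed = run_ensemble(net, [0], 8.0, grid, n, seed=23,
                               engine=engine).snapshot(8.0).ravel()
        sp = SpeciesSet(("X",))
        plain = build_network(sp, [
            make_reaction(sp, {}, {"X": 1}, rate=10.0),
            make_reaction(sp, {"X": 1}, {}, rate=1.0),
        ])
        markov = run_ensemble(plain, [0], 8.0, grid, n, seed=231,
                              engine="direct").snapshot(8.0).ravel()
        assert stats.ks_2samp(delayed, markov).pvalue > 0.01

    def test_no_negative_counts_under_conflict_stress(self, engine):
        """Fast non-delayed degradation racing delayed degradation of one species."""
        sp = SpeciesSet(("X",))
        net = build_network(sp, [
            make_reaction(sp, {}, {"X": 1}, rate=20.0, name="birth"),
            make_reaction(sp, {"X": 1}, {}, rate=10.0, name="fast_death"),
            make_reaction(sp, {"X": 1}, {}, rate=10.0,
                          delay=DelaySpec.completion_only(0.5), name="slow_death"),
        ])
        grid = np.linspace(0, 30, 300)
        ens = run_ensemble(net, [0], 30.0, grid, 10, seed=3, engine=engine)
        assert (ens.states >= 0).all()

    def test_sampled_delay_function(self, engine):
        """Delays drawn from a sampler per firing: Exp(mean tau) lifetimes give
        the same stationary Poisson mean as the M/M/inf queue."""
        sp = SpeciesSet(("X",))
        birth = Reaction(
            reactant_counts=np.zeros(1, dtype=np.int64),
            s_column=np.array([1], dtype=np.int64),
            s_delay_column=np.array([-1], dtype=np.int64),
            rate_constant=5.0,
            delay=DelaySpec.consuming(lambda rng: rng.exponential(2.0)),
        )
        net = build_network(sp, [birth])
        grid = np.arange(0.0, 61.0, 2.0)
        ens = run_ensemble(net, [0], 60.0, grid, 40, seed=29, engine=engine)
        pooled = ens.pooled(np.arange(16.0, 61.0, 4.0)).ravel()
        assert pooled.mean() == pytest.approx(10.0, abs=0.6)


class TestDelayClassSemantics:
    """Deterministic single-firing script separating the two delay classes.

    Drives the firing/completion primitives directly: one X molecule, one
    firing of X -> Y with tau = 5.
    """

    def _setup(self, kind):
        from delaykit.engines.delayed import _Compiled, _fire, _pop_completion
        sp = SpeciesSet(("X", "Y"))
        delay = (DelaySpec.consuming(5.0) if kind == "consuming"
                 else DelaySpec.completion_only(5.0))
        net = build_network(sp, [make_reaction(sp, {"X": 1}, {"Y": 1},
                                               rate=1.0, delay=delay)])
        return _Compiled(net), _fire, _pop_completion

    def test_consuming_removes_reactant_at_firing(self):
        comp, fire, pop = self._setup("consuming")
        counts, queue = [1, 0], PendingEventQueue()
        rng = np.random.default_rng(0)
        fire(0, 2.0, counts, queue, comp, rng)
        # X consumed now, product pending: X + pending(Y) is conserved
        assert counts == [0, 0]
        ev = queue.peek()
        assert ev.completion_time == 7.0 and dict(ev.pairs) == {1: 1}
        pop(7.0, counts, queue, comp, rng)
        assert counts == [0, 1] and len(queue) == 0

    def test_completion_only_defers_everything(self):
        comp, fire, pop = self._setup("completion_only")
        counts, queue = [1, 0], PendingEventQueue()
        rng = np.random.default_rng(0)
        fire(0, 2.0, counts, queue, comp, rng)
        # nothing moves at initiation; both changes arrive at t + tau
        assert counts == [1, 0]
        ev = queue.peek()
        assert ev.completion_time == 7.0 and dict(ev.pairs) == {0: -1, 1: 1}
        pop(7.0, counts, queue, comp, rng)
        assert counts == [0, 1] and len(queue) == 0


def test_cross_delay_engine_agreement(mdinf):
    """Pairwise KS on the M/D/inf marginal at t=12 across the three engines."""
    grid = np.array([0.0, 12.0])
    n = 1200
    snaps = {
        name: run_ensemble(mdinf, [0], 12.0, grid, n, seed=31 + 1000 * k,
                           engine=name).snapshot(12.0).ravel()
        for k, name in enumerate(DELAY_ENGINES)
    }
    names = list(snaps)
    for i in range(len(names)):
        for j in range(i + 1, len(names)):
            p = stats.ks_2samp(snaps[names[i]], snaps[names[j]]).pvalue
            assert p > 0.01, f"{names[i]} vs {names[j]}: p={p}"


def test_zero_delay_mnr_matches_markovian_mnr():
    net = zero_delay_birth_death()
    grid = np.array([0.0, 8.0])
    delayed = run_ensemble(net, [0], 8.0, grid, 1000, seed=5,
                           engine="delay_mnr").snapshot(8.0).ravel()
    sp = SpeciesSet(("X",))
    plain = build_network(sp, [
        make_reaction(sp, {}, {"X": 1}, rate=10.0),
        make_reaction(sp, {"X": 1}, {}, rate=1.0),
    ])
    markov = run_ensemble(plain, [0], 8.0, grid, 1000, seed=55,
                          engine="mnr").snapshot(8.0).ravel()
    assert stats.ks_2samp(delayed, markov).pvalue > 0.01
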