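import numpy as np
import pytest
from scipy.integrate import solve_ivp

from delaykit import (
    ASTParameters,
    AVOGADRO,
    ConversionContext,
    SimulationRequest,
    ast_model,
    ast_ode_rhs,
    bursty_model,
    convert_concentration_model,
    evaluate_propensities,
    refractory_model,
    rna_velocity_model,
    run_ensemble,
    simulate_rna_velocity,
    toggle_switch_model,
)
from delaykit.models import (
    ast_concentration_rhs,
    bursty_burst_propensities,
    refractory_active_fraction,
)
from delaykit.network import SystemState


class TestConversion:
    def test_b_from_volume(self):
        ctx = ConversionContext(volume=1e-20)
        assert ctx.B == pytest.approx(6023.0, rel=1e-12)
        assert ctx.avogadro == 6.023e23

    def test_concentration_to_molecules(self):
        # one concentration unit corresponds to B molecules
        assert 1.0 * ConversionContext(1e-20).B == pytest.approx(6023.0, rel=1e-12)

    def test_b_equal_one_is_identity(self):
        rhs = ast_concentration_rhs(ASTParameters(alpha_S=0.2))
        mol = convert_concentration_model(rhs, 1.0)
        rng = np.random.default_rng(0)
        for _ in range(10):
            x = rng.uniform(0, 5, 4)
            assert np.allclose(mol(0.0, x), rhs(0.0, x), rtol=1e-12)

    def test_nonpositive_b_rejected(self):
        with pytest.raises(ValueError):
            convert_concentration_model(lambda t, x: x, 0.0)
        with pytest.raises(ValueError):
            ConversionContext(volume=-1.0)

    def test_molecule_trajectories_rescale_to_concentration(self):
        """Integrating the molecule system and dividing by B reproduces the
        concentration trajectories (exact algebraic rescaling)."""
        p = ASTParameters(alpha_S=0.2)
        B = 6023.0
        conc = ast_concentration_rhs(p)
        mol = ast_ode_rhs(p, B)
        x0 = np.array([1.0, 0.5, 1.5, 0.2])
        t_eval = np.linspace(0, 30, 20)
        sc = solve_ivp(conc, (0, 30), x0, t_eval=t_eval, rtol=1e-10, atol=1e-12)
        sm = solve_ivp(mol, (0, 30), x0 * B, t_eval=t_eval, rtol=1e-10, atol=1e-8)
        assert np.allclose(sm.y / B, sc.y, rtol=1e-6, atol=1e-7)


class TestBursty:
    def test_truncated_total_rate_matches_geometric_sum(self):
        alpha, b = 0.0282, 3.46
        props = bursty_burst_propensities(alpha, b)
        closed = alpha * b / (1.0 + b)   # = alpha * (1 - 1/(1+b))
        assert abs(props.sum() - closed) < 1e-6
        assert closed == pytest.approx(0.021877, abs=1e-5)

    def test_mean_production_rate_is_alpha_b(self):
        alpha, b = 0.0282, 3.46
        props = bursty_burst_propensities(alpha, b)
        k = np.arange(1, len(props) + 1)
        assert (k * props).sum() == pytest.approx(alpha * b, rel=1e-4)
        assert alpha * b == pytest.approx(0.097572, abs=1e-6)

    def test_small_b_degenerates_gracefully(self):
        props = bursty_burst_propensities(1.0, 1e-4)
        assert (props >= 0).all()
        assert props.sum() < 1e-3

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            bursty_model(alpha=-1.0)
        with pytest.raises(ValueError):
            bursty_model(tau=-5.0)


class TestRefractory:
    def test_gene_state_conservation(self):
        net = refractory_model()
        grid = np.linspace(0, 100, 120)
        ens = run_ensemble(net, [1, 0, 0, 0], 100.0, grid, 5, seed=2,
                           engine="delay_mnr")
        assert (ens.states[:, :, :3].sum(axis=2) == 1).all()

    def test_active_fraction_closed_form(self):
        assert refractory_active_fraction(0.15, 0.1, 0.05) == pytest.approx(0.5455, abs=1e-4)

    def test_no_transcription_when_k4_zero(self):
        net = refractory_model(k4=0.0)
        grid = np.linspace(0, 50, 40)
        ens = run_ensemble(net, [1, 0, 0, 0], 50.0, grid, 3, seed=4,
                           engine="delay_rejection")
        assert (ens.states[:, :, 3] == 0).all()

    def test_invalid_rates(self):
        with pytest.raises(ValueError):
            refractory_model(k1=0.0)


class TestRnaVelocity:
    def test_phase1_means_reach_linear_network_fixed_point(self):
        """E[U] -> alpha/beta and E[S] -> alpha/gamma before the switch."""
        model = rna_velocity_model(alpha=20.0, beta=1.0, gamma=0.5, t_switch=40.0)
        grid = np.linspace(0, 80, 81)
        ens = simulate_rna_velocity(model, 80.0, grid, 250, seed=6)
        u, s = ens.snapshot(40.0).mean(axis=0)
        assert u == pytest.approx(20.0, abs=1.5)
        assert s == pytest.approx(40.0, abs=2.5)

    def test_phase2_decays_to_zero(self):
        model = rna_velocity_model(alpha=20.0, beta=1.0, gamma=0.5, t_switch=30.0)
        grid = np.linspace(0, 90, 90)
        ens = simulate_rna_velocity(model, 90.0, grid, 120, seed=7)
        u, s = ens.mean()[-1]
        assert u < 0.5 and s < 0.8

    def test_pending_removals_survive_the_switch(self):
        """With delayed S degradation, removals scheduled in phase 1 must
        still complete in phase 2 (S keeps draining after alpha -> 0)."""
        model = rna_velocity_model(alpha=20.0, beta=1.0, gamma=0.5,
                                   t_switch=30.0, tau=2.0)
        grid = np.linspace(0, 90, 90)
        ens = simulate_rna_velocity(model, 90.0, grid, 120, seed=8)
        m = ens.mean()
        s_at_switch = m[np.searchsorted(grid, 30.0), 1]
        u, s = m[-1]
        assert s_at_switch > 20.0
        assert u < 0.5 and s < 0.8

    def test_t_final_must_exceed_switch(self):
        with pytest.raises(ValueError):
            simulate_rna_velocity(rna_velocity_model(t_switch=50.0), 40.0,
                                  np.linspace(0, 40, 10), 1)


class TestAst:
    def test_only_productions_active_at_origin(self):
        net = ast_model(ASTParameters(alpha_S=0.05), B=6023.0)
        a = evaluate_propensities(net, SystemState(0.0, [0, 0, 0, 0]))
        names = [r.name for r in net.reactions]
        for name, val in zip(names, a):
            if name.startswith("produce"):
                assert val > 0
            else:
                assert val == 0.0

    def test_degrader_reaction_appended(self):
        net = ast_model(ASTParameters(alpha_S=0.8), B=6023.0,
                        degrader={"k_deg": 2.0, "tau_S": 1.0})
        assert net.n_reactions == 9
        r = net.reactions[-1]
        assert r.delay.kind.value == "completion_only"
        assert r.s_delay_column.tolist() == [0, 0, 0, -1]

    def test_ssa_ensemble_mean_tracks_ode(self):
        """Law of large numbers at B=6023: the SSA ensemble mean follows the
        molecule-based ODE within Monte-Carlo error (scaled-down check)."""
        p = ASTParameters(alpha_S=0.05)
        B = 6023.0
        net = ast_model(p, B=B)
        x0 = (np.array([1.0, 1.0, 1.0, 0.5]) * B).astype(np.int64)
        t_end = 2.0
        grid = np.linspace(0, t_end, 5)
        ens = run_ensemble(net, x0, t_end, grid, 8, seed=12, engine="direct")
        ode = solve_ivp(ast_ode_rhs(p, B), (0, t_end), x0.astype(float),
                        t_eval=grid, rtol=1e-8)
        mean = ens.mean()
        # per-species relative agreement at the final time
        rel = np.abs(mean[-1] - ode.y[:, -1]) / np.maximum(ode.y[:, -1], 1.0)
        assert (rel < 0.05).all(), (mean[-1], ode.y[:, -1])


def test_toggle_switch_network_shape():
    net = toggle_switch_model()
    assert net.species.names == ("U", "V")
    assert net.n_reactions == 4
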