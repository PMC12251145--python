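"""Lineage models: equilibrium elimination, label ODEs, reparameterization."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.integrate import quad, solve_ivp

import tscm_kinetics as tk
from tscm_kinetics.kinetic_models import (
    InfeasibleParameters,
    KineticParams,
    MODEL_IDS,
    POOLS,
    equilibrium_loss_rates,
    fork_invert,
    fork_label_trajectories_pi,
    fork_reparameterize,
    cell_number_rhs,
    label_trajectories,
)

from conftest import random_feasible_params

TIMES = np.array([1.0, 4.0, 10.0, 25.0, 49.0, 70.0, 110.0, 140.0])


class TestEquilibrium:
    def test_model_a_loss_equals_proliferation(self):
        p = KineticParams(model_id="A", p_N=1e-3, p_1=2e-3, p_2=3e-3,
                          R_1=0.05, R_2=0.01)
        assert equilibrium_loss_rates(p) == (1e-3, 2e-3, 3e-3)

    def test_model_c_hand_computed(self):
        p = KineticParams(model_id="C", p_N=1e-3, p_1=2e-3, p_2=3e-3,
                          delta_N=1e-4, k=3.0, frac=0.25, R_1=0.05, R_2=0.01)
        d = equilibrium_loss_rates(p)
        assert d[0] == pytest.approx(1e-3 - 1e-4)
        assert d[1] == pytest.approx(2e-3 + 1e-4 * 8.0 * 0.25 / 0.05)
        assert d[2] == pytest.approx(3e-3 + 1e-4 * 8.0 * 0.75 / 0.01)

    def test_model_d_hand_computed(self):
        p = KineticParams(model_id="D", p_N=1e-3, p_1=2e-3, p_2=3e-3,
                          delta_N=1e-5, delta_1=5e-4, k=4.0, R_1=0.05, R_2=0.01)
        d = equilibrium_loss_rates(p)
        assert d[0] == pytest.approx(1e-3 - 1e-5)
        assert d[1] == pytest.approx(2e-3 + 1e-5 * 16.0 / 0.05 - 5e-4)
        assert d[2] == pytest.approx(3e-3 + 5e-4 * 0.05 / 0.01)

    def test_model_e_mirrors_d(self):
        common = dict(p_N=1e-3, p_1=2e-3, p_2=3e-3, delta_N=1e-5, delta_1=5e-5,
                      k=4.0)
        d_d = equilibrium_loss_rates(
            KineticParams(model_id="D", R_1=0.05, R_2=0.01, **common))
        swapped = dict(common, p_1=common["p_2"], p_2=common["p_1"])
        d_e = equilibrium_loss_rates(
            KineticParams(model_id="E", R_1=0.01, R_2=0.05, **swapped))
        assert d_e[0] == pytest.approx(d_d[0])
        assert d_e[1] == pytest.approx(d_d[2])
        assert d_e[2] == pytest.approx(d_d[1])

    def test_infeasible_raises(self):
        # naive inflow exceeding naive proliferation -> negative d_N
        with pytest.raises(InfeasibleParameters):
            equilibrium_loss_rates(KineticParams(
                model_id="C", p_N=1e-4, p_1=1e-3, p_2=1e-3, delta_N=2e-4,
                k=2.0, frac=0.5, R_1=0.05, R_2=0.01))
        # delta_1 exceeding CD95int inflow -> negative d_1 in model D
        with pytest.raises(InfeasibleParameters):
            equilibrium_loss_rates(KineticParams(
                model_id="D", p_N=1e-3, p_1=1e-4, p_2=1e-3, delta_N=1e-7,
                delta_1=0.1, k=1.0, R_1=0.05, R_2=0.01))

    def test_model_b_not_defined(self):
        p = KineticParams(model_id="B", p_N=1e-3, p_1=1e-3, p_2=1e-3,
                          dstar_N=1e-3, dstar_1=1e-3, dstar_2=1e-3,
                          R_1=0.05, R_2=0.01)
        with pytest.raises(ValueError):
            equilibrium_loss_rates(p)

    def test_pool_constancy_under_equilibrium_rates(self):
        """Equilibrium-derived losses keep pool sizes constant for 500 days."""
        rng = np.random.default_rng(7)
        for model in ("A", "C", "D", "E"):
            for _ in range(3):
                p = random_feasible_params(model, rng)
                y0 = [1.0, p.R_1, p.R_2]
                sol = solve_ivp(cell_number_rhs(p), (0.0, 500.0), y0,
                                rtol=1e-10, atol=1e-12, method="LSODA")
                assert sol.success
                drift = np.abs(sol.y[:, -1] - np.asarray(y0)) / np.asarray(y0)
                assert np.max(drift) < 1e-8, (model, drift)


class TestParamsValidation:
    def test_missing_required_field(self):
        with pytest.raises(ValueError, match="delta_1"):
            KineticParams(model_id="D", p_N=1e-3, p_1=1e-3, p_2=1e-3,
                          delta_N=1e-5, k=3.0, R_1=0.05, R_2=0.01)

    def test_k_out_of_range(self):
        with pytest.raises(ValueError):
            KineticParams(model_id="C", p_N=1e-3, p_1=1e-3, p_2=1e-3,
                          delta_N=1e-5, k=20.0, frac=0.5, R_1=0.05, R_2=0.01)

    def test_unknown_model(self):
        with pytest.raises(ValueError):
            KineticParams(model_id="X", p_N=1e-3, p_1=1e-3, p_2=1e-3,
                          R_1=0.05, R_2=0.01)

    def test_burst_size(self):
        p = KineticParams(model_id="C", p_N=1e-3, p_1=1e-3, p_2=1e-3,
                          delta_N=1e-5, k=10.0, frac=0.5, R_1=0.05, R_2=0.01)
        assert p.burst == 1024.0


class TestLabelTrajectories:
    def test_start_unlabelled(self, truth_d, saliva_truth):
        traj = tk.label_trajectories(truth_d, saliva_truth, 5.2, np.array([0.0, 10.0]))
        for pool in POOLS:
            assert traj[pool].values[0] == pytest.approx(0.0, abs=1e-14)

    def test_zero_amplification_stays_zero(self, truth_d, saliva_truth):
        traj = tk.label_trajectories(truth_d, saliva_truth, 0.0, TIMES)
        for pool in POOLS:
            assert np.max(np.abs(traj[pool].values)) < 1e-14

    def test_model_a_convolution_oracle(self, saliva_truth):
        """L_i(t) = integral of p b_w S(v) e^{-p (t - v)} dv for model A."""
        p = KineticParams(model_id="A", p_N=2e-3, p_1=1e-3, p_2=4e-3,
                          R_1=0.05, R_2=0.01)
        b_w = 5.2
        t_check = np.array([5.0, 30.0, 49.0, 80.0])
        traj = tk.label_trajectories(p, saliva_truth, b_w, t_check)
        for pool, rate in zip(POOLS, (p.p_N, p.p_1, p.p_2)):
            for i, t in enumerate(t_check):
                oracle, _ = quad(
                    lambda v: rate * b_w * saliva_truth(v) * np.exp(-rate * (t - v)),
                    0.0, t, limit=400,
                    points=[x for x in (saliva_truth.t_switch, saliva_truth.t_end)
                            if x < t],
                )
                assert traj[pool].values[i] == pytest.approx(oracle, abs=1e-6)

    def test_exact_vs_ode_random_draws(self, saliva_truth):
        rng = np.random.default_rng(11)
        for model in MODEL_IDS:
            for _ in range(3):
                p = random_feasible_params(model, rng)
                exact = tk.label_trajectories(p, saliva_truth, 5.2, TIMES)
                ode = tk.label_trajectories(p, saliva_truth, 5.2, TIMES,
                                            method="ode")
                for pool in POOLS:
                    assert np.max(np.abs(exact[pool].values - ode[pool].values)) < 1e-6

    def test_model_d_without_flux_reduces_to_a(self, saliva_truth):
        base = dict(p_N=3.1e-4, p_1=8e-4, p_2=2e-3, R_1=0.05, R_2=0.01)
        d0 = KineticParams(model_id="D", delta_N=0.0, delta_1=0.0, k=5.0, **base)
        a = KineticParams(model_id="A", **base)
        td = tk.label_trajectories(d0, saliva_truth, 5.2, TIMES)
        ta = tk.label_trajectories(a, saliva_truth, 5.2, TIMES)
        for pool in POOLS:
            assert np.max(np.abs(td[pool].values - ta[pool].values)) < 1e-10

    def test_model_b_with_dstar_equal_p_reduces_to_a(self, saliva_truth):
        base = dict(p_N=3.1e-4, p_1=8e-4, p_2=2e-3, R_1=0.05, R_2=0.01)
        b = KineticParams(model_id="B", dstar_N=base["p_N"], dstar_1=base["p_1"],
                          dstar_2=base["p_2"], **base)
        a = KineticParams(model_id="A", **base)
        tb = tk.label_trajectories(b, saliva_truth, 5.2, TIMES)
        ta = tk.label_trajectories(a, saliva_truth, 5.2, TIMES)
        for pool in POOLS:
            assert np.max(np.abs(tb[pool].values - ta[pool].values)) < 1e-12

    def test_as_printed_differs_only_downstream(self, truth_d, saliva_truth):
        default = tk.label_trajectories(truth_d, saliva_truth, 5.2, TIMES)
        printed = tk.label_trajectories(truth_d, saliva_truth, 5.2, TIMES,
                                        as_printed=True)
        assert np.allclose(default["TN"].values, printed["TN"].values, atol=1e-14)
        assert np.allclose(default["CD95int"].values, printed["CD95int"].values,
                           atol=1e-14)
        assert not np.allclose(default["CD95hi"].values, printed["CD95hi"].values,
                               atol=1e-6)

    def test_negative_times_rejected(self, truth_d, saliva_truth):
        with pytest.raises(ValueError):
            tk.label_trajectories(truth_d, saliva_truth, 5.2, np.array([-1.0, 5.0]))

    def test_propagator_handles_unsorted_and_duplicate_times(self):
        """The piecewise propagator returns states in request order."""
        from tscm_kinetics._pwlinear import PiecewiseLinearSystem

        # scalar decay with a rate change at t=1: known closed form
        sys = PiecewiseLinearSystem(
            [0.0, 1.0], [np.array([[-1.0]]), np.array([[-2.0]])], np.array([1.0]))
        t = np.array([3.0, 0.5, 3.0, 0.0])
        out = sys.solve(t)[:, 0]
        expected = np.array([np.exp(-1.0) * np.exp(-4.0), np.exp(-0.5),
                             np.exp(-1.0) * np.exp(-4.0), 1.0])
        assert np.allclose(out, expected, atol=1e-14)


class TestForkReparam:
    def test_pi_space_matches_full_model(self, saliva_truth):
        """Model C label curves depend on (p_N, Pi, frac, delta_N) only."""
        p = KineticParams(model_id="C", p_N=3.1e-4, p_1=8e-4, p_2=2e-3,
                          delta_N=1e-6, k=10.3, frac=0.4, R_1=0.05, R_2=0.01)
        pi = fork_reparameterize(p)
        full = tk.label_trajectories(p, saliva_truth, 5.2, TIMES)
        repar = fork_label_trajectories_pi(
            p.p_N, pi.Pi_1, pi.Pi_2, p.frac, p.delta_N,
            p.R_1, p.R_2, saliva_truth, 5.2, TIMES)
        for pool in POOLS:
            assert np.max(np.abs(full[pool].values - repar[pool].values)) < 1e-12

    @given(
        p_1=st.floats(1e-5, 1e-2), p_2=st.floats(1e-5, 1e-2),
        delta_scale=st.floats(0.0, 1.0), k=st.floats(0.0, 15.0),
        frac=st.floats(0.0, 1.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_round_trip(self, p_1, p_2, delta_scale, k, frac):
        p_N = 1e-3
        p = KineticParams(model_id="C", p_N=p_N, p_1=p_1, p_2=p_2,
                          delta_N=delta_scale * p_N, k=k, frac=frac,
                          R_1=0.05, R_2=0.01)
        back = fork_invert(fork_reparameterize(p), p)
        assert back.p_1 == pytest.approx(p_1, rel=1e-12, abs=1e-12)
        assert back.p_2 == pytest.approx(p_2, rel=1e-12, abs=1e-12)

    def test_wrong_model_rejected(self, truth_d):
        with pytest.raises(ValueError):
            fork_reparameterize(truth_d)
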