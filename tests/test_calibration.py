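"""Saliva availability and monocyte amplification-factor calibration."""

import numpy as np
import pytest
from scipy.integrate import quad, solve_ivp

import tscm_kinetics as tk
from tscm_kinetics.calibration import (
    CalibrationError,
    EnrichmentSeries,
    MonocyteParams,
    SalivaModel,
    monocyte_trajectory,
    saliva_enrichment,
)


def dose_target(t, model):
    """Piecewise-constant uptake target u(t) driving w' = delta (u - w)."""
    if t < model.t_switch:
        return model.f
    if t <= model.t_end:
        return model.f / 2.0
    return 0.0


class TestSaliva:
    def test_starts_at_zero(self, saliva_truth):
        assert saliva_truth(0.0) == 0.0

    def test_phase1_closed_form(self, saliva_truth):
        m = saliva_truth
        t = 0.4
        assert saliva_enrichment(t, m) == pytest.approx(
            m.f * (1 - np.exp(-m.delta * t)), abs=1e-15
        )

    def test_continuity_at_phase_changes(self, saliva_truth):
        m = saliva_truth
        eps = 1e-9
        for t in (m.t_switch, m.t_end):
            below, above = m(t - eps), m(t + eps)
            assert abs(above - below) < 1e-10

    def test_matches_uptake_ode(self, saliva_truth):
        """Closed form vs direct integration of w' = delta (u(t) - w)."""
        m = saliva_truth
        t_eval = np.array([0.25, 0.5, 1.0, 3.0, 10.0, 30.0, 49.0, 60.0, 90.0, 140.0])
        sol = solve_ivp(
            lambda t, w: [m.delta * (dose_target(t, m) - w[0])],
            (0.0, 140.0), [0.0], t_eval=t_eval, rtol=1e-11, atol=1e-13,
            method="LSODA", max_step=0.5,
        )
        assert sol.success
        assert np.max(np.abs(sol.y[0] - m(t_eval))) < 1e-8

    def test_washout_is_pure_exponential(self, saliva_truth):
        m = saliva_truth
        s49 = m(m.t_end)
        assert m(80.0) == pytest.approx(s49 * np.exp(-m.delta * (80.0 - m.t_end)),
                                        rel=1e-12)

    def test_negative_time_rejected(self, saliva_truth):
        with pytest.raises(ValueError):
            saliva_enrichment(-1.0, saliva_truth)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(ValueError):
            SalivaModel(f=0.0, delta=0.1)
        with pytest.raises(ValueError):
            SalivaModel(f=0.02, delta=-0.1)
        with pytest.raises(ValueError):
            SalivaModel(f=0.02, delta=0.1, t_switch=50.0, t_end=49.0)


class TestFitSaliva:
    def test_noiseless_recovery(self, saliva_truth):
        t = np.array([0.5, 1.0, 2.0, 4.0, 7.0, 14.0, 28.0, 49.0, 63.0, 98.0])
        series = EnrichmentSeries(times=t, values=saliva_truth(t), population="saliva")
        fit, info = tk.fit_saliva(series)
        assert fit.f == pytest.approx(saliva_truth.f, rel=1e-8)
        assert fit.delta == pytest.approx(saliva_truth.delta, rel=1e-8)
        assert info["success"]

    def test_noisy_recovery_median_within_5_percent(self, saliva_truth):
        t = np.array([0.5, 1.0, 2.0, 4.0, 7.0, 14.0, 21.0, 28.0, 42.0, 49.0,
                      56.0, 63.0, 77.0, 98.0])
        clean = saliva_truth(t)
        rng = np.random.default_rng(12345)
        fs, deltas = [], []
        for _ in range(200):
            noisy = clean + 0.0005 * rng.standard_normal(t.size)
            series = EnrichmentSeries(times=t, values=noisy, population="saliva")
            fit, _ = tk.fit_saliva(series)
            fs.append(fit.f)
            deltas.append(fit.delta)
        assert np.median(fs) == pytest.approx(saliva_truth.f, rel=0.05)
        assert np.median(deltas) == pytest.approx(saliva_truth.delta, rel=0.05)

    def test_too_few_points(self, saliva_truth):
        series = EnrichmentSeries(times=np.array([1.0, 2.0]),
                                  values=np.array([0.01, 0.01]))
        with pytest.raises(CalibrationError):
            tk.fit_saliva(series)

    def test_all_zero_series(self):
        series = EnrichmentSeries(times=np.arange(1.0, 9.0),
                                  values=np.zeros(8))
        with pytest.raises(CalibrationError):
            tk.fit_saliva(series)


def monocyte_convolution_oracle(t, params, saliva):
    """Blood enrichment via nested convolution integrals.

    L_M(u) = integral of p_m b_w S(v) e^{-r1 (u - v)} dv, and
    L_B(t) = integral of r2 L_M(s - delay) e^{-r2 (t - s)} ds
    (using r1 M/B = r2 from flow conservation).
    """

    def L_M(u):
        if u <= 0:
            return 0.0
        val, _ = quad(
            lambda v: params.p_m * params.b_w * saliva(v)
            * np.exp(-params.r1 * (u - v)),
            0.0, u, limit=400,
            points=[p for p in (saliva.t_switch, saliva.t_end) if p < u],
        )
        return val

    if t <= params.delay:
        return 0.0
    val, _ = quad(
        lambda s: params.r2 * L_M(s - params.delay) * np.exp(-params.r2 * (t - s)),
        params.delay, t, limit=400,
    )
    return val


class TestMonocyte:
    def test_matches_convolution_oracle(self, saliva_truth, monocyte_truth):
        times = np.array([1.0, 3.0, 7.0, 20.0, 49.0, 60.0])
        pred = monocyte_trajectory(times, monocyte_truth, saliva_truth).values
        oracle = [monocyte_convolution_oracle(t, monocyte_truth, saliva_truth)
                  for t in times]
        assert np.max(np.abs(pred - np.asarray(oracle))) < 1e-6

    def test_zero_before_delay(self, saliva_truth, monocyte_truth):
        times = np.array([0.0, monocyte_truth.delay * 0.5, monocyte_truth.delay])
        pred = monocyte_trajectory(times, monocyte_truth, saliva_truth).values
        assert np.all(pred <= 1e-12)

    def test_fast_turnover_tracks_amplified_saliva(self, saliva_truth):
        """With fast turnover, blood enrichment tracks b_w * S(t - delay)."""
        fast = MonocyteParams(b_w=5.2, r2=8.0, delay=0.0)
        t = np.array([30.0, 45.0])
        pred = monocyte_trajectory(t, fast, saliva_truth).values
        assert pred == pytest.approx(fast.b_w * saliva_truth(t), rel=0.03)

    def test_equilibrium_identities(self, monocyte_truth):
        assert monocyte_truth.r1 == pytest.approx(
            monocyte_truth.r2 / monocyte_truth.m_over_b)
        assert monocyte_truth.p_m == monocyte_truth.r1

    def test_noiseless_recovery(self, saliva_truth, monocyte_truth):
        t = np.array([2.0, 4.0, 7.0, 14.0, 21.0, 28.0, 42.0, 49.0, 56.0, 70.0])
        vals = monocyte_trajectory(t, monocyte_truth, saliva_truth).values
        series = EnrichmentSeries(times=t, values=vals, population="monocytes")
        fit, info = tk.fit_monocyte(series, saliva_truth)
        assert fit.b_w == pytest.approx(monocyte_truth.b_w, rel=1e-6)
        assert fit.r2 == pytest.approx(monocyte_truth.r2, rel=1e-6)

    def test_bw_invariant_to_m_over_b_and_delay(self, saliva_truth, monocyte_truth):
        """b_w is identified by the plateau, not the compartment bookkeeping."""
        t = np.array([2.0, 4.0, 7.0, 14.0, 21.0, 28.0, 42.0, 49.0, 56.0, 70.0])
        vals = monocyte_trajectory(t, monocyte_truth, saliva_truth).values
        series = EnrichmentSeries(times=t, values=vals, population="monocytes")
        ref, _ = tk.fit_monocyte(series, saliva_truth)
        alt_ratio, _ = tk.fit_monocyte(series, saliva_truth, m_over_b=5.0)
        alt_delay, _ = tk.fit_monocyte(series, saliva_truth, delay=3.0)
        assert alt_ratio.b_w == pytest.approx(ref.b_w, rel=0.01)
        assert alt_delay.b_w == pytest.approx(ref.b_w, rel=0.01)

    def test_requires_saliva_model(self, study_d):
        bundle, _ = study_d
        with pytest.raises(CalibrationError):
            tk.fit_monocyte(bundle.monocyte, None)


class TestEnrichmentSeries:
    def test_rejects_non_monotone_times(self):
        with pytest.raises(ValueError):
            EnrichmentSeries(times=np.array([1.0, 1.0]), values=np.zeros(2))
        with pytest.raises(ValueError):
            EnrichmentSeries(times=np.array([2.0, 1.0]), values=np.zeros(2))

    def test_rejects_negative_sd(self):
        with pytest.raises(ValueError):
            EnrichmentSeries(times=np.array([1.0]), values=np.array([0.1]),
                             sd=np.array([-1.0]))

    def test_calibrate_bundle_recovers_truth(self, noiseless_study_d, saliva_truth,
                                             monocyte_truth):
        bundle, _ = noiseless_study_d
        assert bundle.saliva_model.f == pytest.approx(saliva_truth.f, rel=1e-6)
        assert bundle.saliva_model.delta == pytest.approx(saliva_truth.delta, rel=1e-6)
        assert bundle.monocyte_params.b_w == pytest.approx(monocyte_truth.b_w, rel=1e-4)
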