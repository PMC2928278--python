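"""Batch-growth simulation, normalization, comparison, rate fitting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from warburg.dfba import (
    GrowthCurve,
    GrowthSimConfig,
    MeasurementMatrix,
    compare_curves,
    fit_growth_rate,
    normalize_curve,
    scale_substrate,
    simulate_growth,
)
from warburg.synth import GrowthNoiseModel, generate_growth_measurements


def exponential_curve(mu=0.03, X0=0.01, t_max=120.0, n=121):
    t = np.linspace(0, t_max, n)
    return GrowthCurve(
        times=t,
        X=X0 * np.exp(mu * t),
        S=np.linspace(20, 10, n),
        mu=np.full(n - 1, mu),
        uptake=np.ones(n - 1),
    )


class TestScaleSubstrate:
    def test_unit_denominators(self):
        assert scale_substrate(10, 1, 1) == pytest.approx(10)

    def test_no_substrate(self):
        assert scale_substrate(0, 0.3, 2.0) == 0

    def test_homogeneity_in_biomass(self):
        assert scale_substrate(7, 2 * 0.4, 1.5) == pytest.approx(
            0.5 * scale_substrate(7, 0.4, 1.5)
        )

    @pytest.mark.parametrize("X,dt", [(0, 1), (-1, 1), (1, 0), (1, -2)])
    def test_domain_errors(self, X, dt):
        with pytest.raises(ValueError):
            scale_substrate(5, X, dt)


class TestSimulateGrowth:
    def test_no_glucose_means_no_growth(self, core_net, core_objective):
        curve = simulate_growth(core_net, core_objective, GrowthSimConfig(S0=0.0, t_max=24))
        assert np.allclose(curve.X, curve.X[0])
        assert np.all(curve.mu == 0)

    def test_exponential_closed_form_under_unlimited_glucose(self, core_net, core_objective):
        cfg = GrowthSimConfig(S0=1e9, t_max=48.0)
        curve = simulate_growth(core_net, core_objective, cfg)
        mu = curve.mu[0]
        assert np.all(np.abs(curve.mu - mu) < 1e-12)
        expected = cfg.X0 * np.exp(mu * curve.times)
        np.testing.assert_allclose(curve.X, expected, rtol=1e-6)

    def test_default_run_exhausts_glucose_and_plateaus(self, core_net, core_objective):
        curve = simulate_growth(core_net, core_objective)
        assert curve.S[-1] == pytest.approx(0.0, abs=1e-9)
        assert np.all(np.diff(curve.S) <= 1e-9)
        assert np.all(np.diff(curve.X) >= -1e-12)
        # density beyond exhaustion holds the plateau
        after = curve.density_at(np.array([curve.times[-1] + 24.0]))
        assert after[0] == pytest.approx(curve.X[-1])

    def test_substrate_conservation(self, core_net, core_objective):
        cfg = GrowthSimConfig()
        curve = simulate_growth(core_net, core_objective, cfg)
        # X-weighted integral of uptake over each step equals S0 - S(final)
        consumed = cfg.S0 - curve.S[-1]
        integral = 0.0
        for k in range(len(curve.mu)):
            dt = curve.times[k + 1] - curve.times[k]
            mu, su, X = curve.mu[k], curve.uptake[k], curve.X[k]
            if mu > 1e-12:
                integral += su / mu * X * np.expm1(mu * dt)
            else:
                integral += su * X * dt
        assert integral == pytest.approx(consumed, rel=1e-6)

    def test_halving_dt_is_stable(self, core_net, core_objective):
        coarse = simulate_growth(core_net, core_objective, GrowthSimConfig(dt=1.0))
        fine = simulate_growth(core_net, core_objective, GrowthSimConfig(dt=0.5))
        assert abs(fine.X[-1] - coarse.X[-1]) / coarse.X[-1] < 0.01

    def test_euler_matches_analytic_at_small_dt(self, core_net, core_objective):
        a = simulate_growth(core_net, core_objective, GrowthSimConfig(dt=0.25))
        e = simulate_growth(
            core_net, core_objective, GrowthSimConfig(dt=0.25, integration="euler")
        )
        assert abs(a.X[-1] - e.X[-1]) / a.X[-1] < 0.02

    def test_unknown_substrate_reaction(self, core_net, core_objective):
        with pytest.raises(KeyError):
            simulate_growth(
                core_net, core_objective, GrowthSimConfig(substrate_reaction="NOPE")
            )


class TestNormalizeCurve:
    def test_arithmetic(self):
        np.testing.assert_allclose(
            normalize_curve([1, 2, 3, 4, 5]), [0, 0.25, 0.5, 0.75, 1]
        )

    def test_order_preserved(self):
        np.testing.assert_allclose(normalize_curve([5, 1]), [1, 0])

    def test_degenerate_curve_raises(self):
        with pytest.raises(ValueError):
            normalize_curve([2.0, 2.0, 2.0])

    @given(
        st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=20).filter(
            lambda v: max(v) - min(v) > 1e-6
        ),
        st.floats(0.1, 10),
        st.floats(-100, 100),
    )
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_affine_invariance_and_idempotence(self, values, a, b):
        v = np.array(values)
        base = normalize_curve(v)
        np.testing.assert_allclose(normalize_curve(a * v + b), base, atol=1e-6)
        np.testing.assert_allclose(normalize_curve(base), base, atol=1e-12)
        assert base.min() == pytest.approx(0) and base.max() == pytest.approx(1)


class TestCompareCurves:
    def test_identity_has_zero_rmse(self):
        curve = exponential_curve()
        times = 24.0 * np.arange(1, 6)
        G = np.tile(curve.density_at(times)[:, None], (1, 6))
        rep = compare_curves(curve, MeasurementMatrix(times=times, G=G))
        assert rep.rmse == pytest.approx(0.0, abs=1e-12)

    def test_noise_bounded_rmse(self, core_net, core_objective):
        curve = simulate_growth(core_net, core_objective)
        noise = GrowthNoiseModel(cv=0.1, seed=11)
        rep = compare_curves(curve, generate_growth_measurements(curve, noise))
        assert rep.rmse < noise.cv

    def test_replicate_cv_matches_definition(self):
        G = np.array([[1.0, 2.0, 3.0], [4.0, 4.0, 4.0]])
        m = MeasurementMatrix(times=np.array([24.0, 48.0]), G=G)
        assert m.cv[0] == pytest.approx(np.std([1, 2, 3], ddof=1) / 2.0)
        assert m.cv[1] == pytest.approx(0.0)

    def test_too_few_time_points(self):
        curve = exponential_curve()
        with pytest.raises(ValueError):
            compare_curves(
                curve, MeasurementMatrix(times=np.array([24.0]), G=np.ones((1, 3)))
            )


class TestFitGrowthRate:
    def test_noiseless_exponential_recovered_exactly(self):
        curve = exponential_curve(mu=0.03)
        times = 24.0 * np.arange(1, 6)
        G = np.tile(curve.density_at(times)[:, None], (1, 6))
        fit = fit_growth_rate(MeasurementMatrix(times=times, G=G))
        assert fit.mu_hat == pytest.approx(0.03, abs=1e-8)
        assert not fit.plateau_trimmed

    def test_monte_carlo_recovery_within_15_percent(self):
        curve = exponential_curve(mu=0.03)
        hits = 0
        for seed in range(200):
            meas = generate_growth_measurements(curve, GrowthNoiseModel(seed=seed))
            fit = fit_growth_rate(meas)
            if abs(fit.mu_hat - 0.03) <= 0.15 * 0.03:
                hits += 1
        assert hits >= 190  # >= 95% of 200 seeds

    def test_plateau_is_trimmed_and_flagged(self, core_net, core_objective):
        curve = simulate_growth(core_net, core_objective)
        meas = generate_growth_measurements(curve, GrowthNoiseModel(cv=0.0))
        fit = fit_growth_rate(meas)
        assert fit.plateau_trimmed
        assert fit.window[1] < len(meas.times)

    def test_non_positive_means_raise(self):
        m = MeasurementMatrix(times=np.array([24.0, 48, 72]), G=np.array([[1.0], [0.0], [2.0]]))
        with pytest.raises(ValueError):
            fit_growth_rate(m)
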