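"""Flexible parametric survival model: spline basis, fitting, prediction."""

import numpy as np
import pytest

from crcgrs.fpsm import (
    SplineBasisSpec,
    default_knots,
    fit_fpsm,
    predict_risk,
    predict_survival,
    predicted_hr,
    rcs_basis,
    rcs_derivative,
)
from crcgrs.simulate import simulate_event_times


@pytest.fixture
def spec2():
    return SplineBasisSpec(df=2, boundary_knots=(-1.0, 2.0), interior_knots=(0.5,))


class TestSplineBasis:
    def test_df1_is_identity(self):
        spec = SplineBasisSpec(df=1, boundary_knots=(0.0, 1.0))
        x = np.linspace(-2, 3, 20)
        assert np.array_equal(rcs_basis(x, spec), x[:, None])

    def test_unordered_knots_rejected(self):
        with pytest.raises(ValueError):
            SplineBasisSpec(df=2, boundary_knots=(1.0, -1.0), interior_knots=(0.0,))
        with pytest.raises(ValueError):
            SplineBasisSpec(df=2, boundary_knots=(0.0, 1.0), interior_knots=(2.0,))
        with pytest.raises(ValueError):
            SplineBasisSpec(df=3, boundary_knots=(0.0, 1.0), interior_knots=(0.5,))

    @pytest.mark.parametrize("knot_idx", [0, 1])
    def test_second_derivative_continuous_at_boundary_knots(self, spec2, knot_idx):
        k = spec2.boundary_knots[knot_idx]
        eps = 1e-4
        def second_deriv(x0):
            h = 1e-4
            f = lambda z: rcs_basis(np.array([z]), spec2)[0]
            return (f(x0 + h) - 2 * f(x0) + f(x0 - h)) / h**2
        gap = np.abs(second_deriv(k + eps) - second_deriv(k - eps))
        assert np.all(gap < 1e-6 * max(1.0, np.abs(second_deriv(k - eps)).max()) + 1e-4)

    def test_linear_beyond_boundary_knots(self, spec2):
        hi = spec2.boundary_knots[1]
        x1, x2 = hi + 1.0, hi + 2.0
        b1 = rcs_basis(np.array([x1]), spec2)[0]
        b2 = rcs_basis(np.array([x2]), spec2)[0]
        slope = rcs_derivative(np.array([hi + 0.5]), spec2)[0]
        far = rcs_basis(np.array([hi + 10.0]), spec2)[0]
        extrapolated = b1 + slope * (hi + 10.0 - x1)
        assert np.allclose(far, extrapolated, atol=1e-8)
        # slope constant in the linear region
        assert np.allclose((b2 - b1) / (x2 - x1), slope, atol=1e-10)


class TestFitting:
    def test_exponential_data_recovers_weibull_shape_one(self, exp_survival_data):
        t, e = exp_survival_data
        fit = fit_fpsm(t, e, df=1)
        shape = fit.gamma[1]
        se_shape = np.sqrt(fit.covariance[1, 1])
        assert abs(shape - 1.0) < 3 * se_shape
        scale = np.exp(-fit.gamma[0] / fit.gamma[1])
        assert scale == pytest.approx(10.0, rel=0.1)

    def test_df1_loglik_matches_lifelines_weibull(self, exp_survival_data):
        lifelines = pytest.importorskip("lifelines")
        t, e = exp_survival_data
        fit = fit_fpsm(t, e, df=1)
        wf = lifelines.WeibullFitter().fit(t, e)
        # lifelines parametrises S(t) = exp(-(t/lambda)^rho)
        assert fit.loglik == pytest.approx(wf.log_likelihood_, rel=1e-4)
        assert fit.gamma[1] == pytest.approx(wf.rho_, rel=1e-3)
        assert np.exp(-fit.gamma[0] / fit.gamma[1]) == pytest.approx(
            wf.lambda_, rel=1e-3
        )

    def test_covariate_log_hr_recovery(self):
        rng = np.random.default_rng(3)
        x = rng.normal(0.0, 1.0, 20000)
        t, e = simulate_event_times(0.5 * x, 1.2, 30.0, 10.0, 0.01, seed=4)
        fit = fit_fpsm(t, e, covariates=x[:, None], df=2)
        assert abs(fit.beta[0] - 0.5) < 3 * fit.beta_se[0]

    def test_no_events_rejected(self):
        with pytest.raises(ValueError, match="event"):
            fit_fpsm(np.ones(50), np.zeros(50), df=1)

    def test_nonpositive_times_rejected(self):
        with pytest.raises(ValueError):
            fit_fpsm(np.array([0.0, 1.0]), np.array([1, 1]), df=1)

    def test_nested_df_never_decreases_loglik(self, exp_survival_data):
        # model spaces nest only when the knot sequences nest, so the df=3
        # fit keeps the df=2 interior knot and adds one more
        t, e = exp_survival_data
        ll1 = fit_fpsm(t, e, df=1).loglik
        fit2 = fit_fpsm(t, e, df=2)
        lo, hi = fit2.basis.boundary_knots
        med = fit2.basis.interior_knots[0]
        extra = (lo + med) / 2.0
        spec3 = SplineBasisSpec(
            df=3, boundary_knots=(lo, hi), interior_knots=tuple(sorted((med, extra)))
        )
        ll3 = fit_fpsm(t, e, df=3, knots=spec3).loglik
        assert fit2.loglik >= ll1 - 1e-6
        assert ll3 >= fit2.loglik - 1e-6

    def test_optimum_beats_random_perturbations(self, exp_survival_data):
        t, e = exp_survival_data
        fit = fit_fpsm(t, e, df=2)
        from crcgrs.fpsm import _negloglik_and_grad, rcs_basis, rcs_derivative

        log_t = np.log(t)
        B = np.column_stack([np.ones_like(log_t), rcs_basis(log_t, fit.basis)])
        dB = np.column_stack([np.zeros_like(log_t), rcs_derivative(log_t, fit.basis)])
        X = np.empty((t.size, 0))
        off = np.zeros_like(t)
        theta = fit.params
        rng = np.random.default_rng(0)
        for _ in range(100):
            pert = theta + rng.normal(0.0, 0.05, theta.size)
            nll, _ = _negloglik_and_grad(pert, B, dB, X, off, e.astype(float), log_t)
            assert -nll <= fit.loglik + 1e-8


class TestPrediction:
    def test_survival_tends_to_one_at_small_t(self, exp_survival_data):
        t, e = exp_survival_data
        fit = fit_fpsm(t, e, df=2)
        tiny = np.exp(fit.basis.boundary_knots[0]) * 1e-6
        assert predict_survival(fit, None, tiny)[0] > 1.0 - 1e-4

    def test_nonpositive_time_rejected(self, exp_survival_data):
        t, e = exp_survival_data
        fit = fit_fpsm(t, e, df=1)
        with pytest.raises(ValueError):
            predict_survival(fit, None, 0.0)

    def test_proportional_hazards_identity(self):
        rng = np.random.default_rng(8)
        x = rng.normal(0, 1, 4000)
        t, e = simulate_event_times(0.4 * x, 1.0, 20.0, 15.0, 0.0, seed=9)
        fit = fit_fpsm(t, e, covariates=x[:, None], df=2)
        s1 = predict_survival(fit, np.array([[2.0]]), 5.0)
        s0 = predict_survival(fit, np.array([[0.0]]), 5.0)
        log_h_diff = np.log(-np.log(s1)) - np.log(-np.log(s0))
        assert log_h_diff == pytest.approx(2.0 * fit.beta[0], abs=1e-10)

    def test_df1_exponential_matches_closed_form(self):
        # at n=20000 the Weibull shape estimate is close enough to 1 that
        # the fitted survival tracks the exponential MLE curve
        t, e = simulate_event_times(
            np.zeros(20000), 1.0, 10.0, 500.0, 0.0, seed=42
        )
        fit = fit_fpsm(t, e, df=1)
        lam = e.sum() / t.sum()  # exponential MLE
        grid = np.linspace(0.5, 30.0, 40)
        pred = predict_survival(fit, None, grid)
        assert np.allclose(pred, np.exp(-lam * grid), atol=5e-3)

    def test_survival_monotone_in_time(self, exp_survival_data):
        t, e = exp_survival_data
        fit = fit_fpsm(t, e, df=3)
        grid = np.linspace(0.1, 40.0, 300)
        s = predict_survival(fit, None, grid)
        assert np.all(np.diff(s) <= 1e-12)

    def test_risk_complements_survival(self, exp_survival_data):
        t, e = exp_survival_data
        fit = fit_fpsm(t, e, df=1)
        assert predict_risk(fit, None, 5.0)[0] == pytest.approx(
            1.0 - predict_survival(fit, None, 5.0)[0]
        )


class TestPredictedHR:
    @pytest.fixture
    def fitted(self):
        rng = np.random.default_rng(11)
        x = rng.normal(0, 1, 3000)
        t, e = simulate_event_times(0.7 * x, 1.0, 15.0, 20.0, 0.0, seed=12)
        return fit_fpsm(t, e, covariates=x[:, None], df=2)

    def test_identical_rows_give_unit_hr(self, fitted):
        assert predicted_hr(fitted, [1.3], [1.3]) == 1.0

    def test_hand_computed_hr(self, fitted):
        hr = predicted_hr(fitted, [1.0], [0.0])
        assert hr == pytest.approx(np.exp(fitted.beta[0]))

    def test_reciprocity(self, fitted):
        assert predicted_hr(fitted, [0.4], [-0.6]) * predicted_hr(
            fitted, [-0.6], [0.4]
        ) == pytest.approx(1.0)


def test_default_knots_df2_interior_at_median():
    x = np.log(np.array([1.0, 2.0, 3.0, 4.0, 5.0]))
    spec = default_knots(x, df=2)
    assert spec.boundary_knots == (x.min(), x.max())
    assert spec.interior_knots == (np.median(x),)
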