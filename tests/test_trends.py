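"""Fixed-intercept slope estimation and its oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phefluxes import (
    estimate_consumption_rate,
    evaluate_trend,
    fit_fixed_intercept_slope,
    mean_tyrosine_labelling,
)
from phefluxes.trends import DegenerateDesignError, EmissionMonotonicityError, LinearTrend


def brute_force_slope(times, values, intercept, span=50.0, n=2_000_001):
    """Independent oracle: grid search minimising the SSR over the slope."""
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    slopes = np.linspace(-span, span, n)
    ssr = ((y - intercept)[None, :] - slopes[:, None] * t[None, :]) ** 2
    return slopes[ssr.sum(axis=1).argmin()]


class TestFixedInterceptSlope:
    def test_exact_affine_data_recovers_slope_with_zero_variance(self):
        trend = fit_fixed_intercept_slope([2, 4, 6], [110, 120, 130], 100.0)
        assert trend.slope == pytest.approx(5.0, abs=1e-12)
        assert trend.slope_variance == pytest.approx(0.0, abs=1e-20)

    def test_constant_series_gives_zero_slope(self):
        trend = fit_fixed_intercept_slope([2, 4, 6], [100, 100, 100], 100.0)
        assert trend.slope == 0.0
        assert trend.slope_variance == 0.0

    def test_hand_computed_least_squares_with_residuals(self):
        # b = sum(t*(y-100))/sum(t^2) = 288/56 = 36/7;
        # SSR/(n-1)/sum(t^2) with n-1 = 2 degrees of freedom
        trend = fit_fixed_intercept_slope([2, 4, 6], [112, 118, 132], 100.0)
        assert trend.slope == pytest.approx(36 / 7, rel=1e-12)
        assert trend.slope_variance == pytest.approx(0.0969387755, rel=1e-6)
        assert trend.n_points == 3

    def test_agrees_with_statsmodels_no_intercept_fit(self):
        # shifting out the fixed intercept turns the model into y' = b*t,
        # which a general-purpose OLS routine fits without an intercept term
        sm = pytest.importorskip("statsmodels.api")
        t = np.array([1.0, 2.0, 4.0, 5.5, 6.0])
        y = np.array([3.1, 8.2, 11.9, 17.4, 18.2])
        trend = fit_fixed_intercept_slope(t, y, intercept=1.0)
        ols = sm.OLS(y - 1.0, t[:, None]).fit()
        assert trend.slope == pytest.approx(ols.params[0], rel=1e-10)
        assert trend.slope_variance == pytest.approx(ols.bse[0] ** 2, rel=1e-10)

    def test_agrees_with_brute_force_ssr_minimiser(self):
        t = [2.0, 4.0, 6.0]
        y = [115.0, 117.0, 136.0]
        trend = fit_fixed_intercept_slope(t, y, 100.0)
        assert trend.slope == pytest.approx(
            brute_force_slope(t, y, 100.0), abs=1e-4
        )

    def test_degenerate_designs_raise(self):
        with pytest.raises(DegenerateDesignError):
            fit_fixed_intercept_slope([0.0, 0.0], [1.0, 2.0], 0.0)
        with pytest.raises(ValueError):
            fit_fixed_intercept_slope([2.0], [1.0], 0.0)

    @settings(derandomize=True, max_examples=50, deadline=None)
    @given(
        scale=st.floats(0.1, 10.0),
        shift=st.floats(-50.0, 50.0),
        seed=st.integers(0, 10_000),
    )
    def test_estimator_linearity_and_shift_invariance(self, scale, shift, seed):
        rng = np.random.default_rng(seed)
        t = np.array([2.0, 4.0, 6.0])
        y = 100.0 + 5.0 * t + rng.normal(0, 1, 3)
        base = fit_fixed_intercept_slope(t, y, 100.0)
        scaled = fit_fixed_intercept_slope(t, scale * y, scale * 100.0)
        assert scaled.slope == pytest.approx(scale * base.slope, rel=1e-9)
        shifted = fit_fixed_intercept_slope(t, y + shift, 100.0 + shift)
        assert shifted.slope == pytest.approx(base.slope, rel=1e-9, abs=1e-12)

    def test_slope_variance_zero_iff_residuals_zero(self):
        exact = fit_fixed_intercept_slope([1, 2, 3], [2, 4, 6], 0.0)
        assert exact.slope_variance == 0.0
        noisy = fit_fixed_intercept_slope([1, 2, 3], [2, 4.5, 6], 0.0)
        assert noisy.slope_variance > 0.0


class TestEvaluateTrend:
    def test_affine_evaluation(self):
        trend = LinearTrend(5.0, 0.0, 100.0, 0.0, 3)
        np.testing.assert_allclose(
            evaluate_trend(trend, [0, 3, 6]), [100.0, 115.0, 130.0]
        )

    def test_six_minute_grid_endpoints(self):
        trend = LinearTrend(5.0, 0.0, 100.0, 0.0, 3)
        grid = 0.1 * np.arange(61)
        values = evaluate_trend(trend, grid)
        assert values.size == 61
        assert values[0] == 100.0
        assert values[-1] == pytest.approx(130.0)

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            evaluate_trend(LinearTrend(0.0, 0.0, 1.0, 0.0, 2), [])


class TestTyrosineLabelling:
    def test_mean_and_variance_of_mean(self):
        mean, var = mean_tyrosine_labelling([0.84, 0.86, 0.85])
        assert mean == pytest.approx(0.85)
        assert var == pytest.approx(np.var([0.84, 0.86, 0.85], ddof=1) / 3)

    @pytest.mark.parametrize("series", [[0.8], [0.7, 0.7, 0.7]])
    def test_degenerate_series_have_zero_variance(self, series):
        mean, var = mean_tyrosine_labelling(series)
        assert mean == pytest.approx(series[0])
        assert var == pytest.approx(0.0, abs=1e-30)

    def test_empty_or_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mean_tyrosine_labelling([])
        with pytest.raises(ValueError):
            mean_tyrosine_labelling([0.5, 1.2])


class TestConsumptionRate:
    def test_exact_linear_emission(self):
        trend = estimate_consumption_rate([2, 4, 6], [20, 40, 60])
        assert trend.slope == pytest.approx(10.0, rel=1e-12)
        assert trend.intercept == 0.0
        assert trend.slope_variance == pytest.approx(0.0, abs=1e-20)

    def test_zero_emission_gives_zero_rate(self):
        assert estimate_consumption_rate([2, 4, 6], [0, 0, 0]).slope == 0.0

    def test_rate_scales_linearly_with_emission(self):
        y = np.array([21.0, 39.0, 62.0])
        base = estimate_consumption_rate([2, 4, 6], y).slope
        doubled = estimate_consumption_rate([2, 4, 6], 2 * y).slope
        assert doubled == pytest.approx(2 * base, rel=1e-12)

    def test_decreasing_emission_warns_by_default_raises_in_strict(self):
        with pytest.warns(UserWarning):
            estimate_consumption_rate([2, 4, 6], [20, 18, 25])
        with pytest.raises(EmissionMonotonicityError):
            estimate_consumption_rate([2, 4, 6], [20, 18, 25], strict=True)
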