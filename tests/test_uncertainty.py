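"""Delta-method propagation against hand results and the Monte-Carlo oracle."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phefluxes import flux_variances, monte_carlo_flux_variance, propagate_variance
from phefluxes.trends import LinearTrend
from phefluxes.uncertainty import VarianceBudget

GRID = 0.1 * np.arange(61)


def _trend(slope, var, intercept):
    return LinearTrend(slope, var, intercept, 0.0, 3)


class TestPropagateVariance:
    def test_product_example_by_hand(self):
        # y = x1*x2 at (3, 5): partials (5, 3); 25*0.04 + 9*0.09 = 1.81
        assert propagate_variance([5.0, 3.0], [0.04, 0.09]) == pytest.approx(1.81)

    def test_product_example_against_monte_carlo(self):
        rng = np.random.default_rng(7)
        x1 = rng.normal(3.0, 0.2, 1_000_000)
        x2 = rng.normal(5.0, 0.3, 1_000_000)
        assert propagate_variance([5.0, 3.0], [0.04, 0.09]) == pytest.approx(
            np.var(x1 * x2, ddof=1), rel=0.01
        )

    def test_zero_variances_and_additivity(self):
        assert propagate_variance([2.0, -4.0], [0.0, 0.0]) == 0.0
        assert propagate_variance([1.0, 1.0], [0.3, 0.5]) == pytest.approx(0.8)

    def test_length_mismatch_and_negative_variance_rejected(self):
        with pytest.raises(ValueError):
            propagate_variance([1.0], [0.1, 0.2])
        with pytest.raises(ValueError):
            propagate_variance([1.0, 1.0], [0.1, -0.2])

    @settings(derandomize=True, max_examples=40, deadline=None)
    @given(
        partials=st.lists(st.floats(-5, 5), min_size=2, max_size=6),
        k=st.floats(0.1, 10.0),
        seed=st.integers(0, 1000),
    )
    def test_permutation_invariance_and_unit_scaling(self, partials, k, seed):
        rng = np.random.default_rng(seed)
        variances = rng.uniform(0.0, 2.0, len(partials))
        base = propagate_variance(partials, variances)
        perm = rng.permutation(len(partials))
        assert propagate_variance(
            np.asarray(partials)[perm], variances[perm]
        ) == pytest.approx(base, rel=1e-12, abs=1e-15)
        # rescaling input i's units by k: partial /= k, variance *= k^2
        scaled_p = np.asarray(partials, float).copy()
        scaled_v = variances.copy()
        scaled_p[0] /= k
        scaled_v[0] *= k**2
        assert propagate_variance(scaled_p, scaled_v) == pytest.approx(
            base, rel=1e-9, abs=1e-15
        )

    def test_variance_budget_totals(self):
        budget = VarianceBudget(("a", "b"), (0.04, 0.09), (5.0, 3.0))
        assert budget.output_variance == pytest.approx(1.81)
        with pytest.raises(ValueError):
            VarianceBudget(("a",), (0.1, 0.2), (1.0, 1.0))


class TestFluxVariances:
    def test_all_zero_inputs_give_zero_trajectory_variance(self):
        v1v, v2v = flux_variances(
            _trend(5.0, 0.0, 100.0), _trend(0.02, 0.0, 0.0), 0.8, 0.0, 10.0, 0.0, GRID
        )
        np.testing.assert_array_equal(v1v, 0.0)
        np.testing.assert_array_equal(v2v, 0.0)

    def test_only_vc_variance_with_zero_enrichment(self):
        """With f ≡ 0 the v2 equation has no vc sensitivity, so all of
        Var(vc) lands on v1 (enrichment-only balance)."""
        v1v, v2v = flux_variances(
            _trend(5.0, 0.0, 100.0),
            _trend(0.0, 0.0, 0.0),
            0.8,
            0.0,
            10.0,
            0.25,
            GRID,
            balance="enrichment_only",
        )
        np.testing.assert_allclose(v2v, 0.0, atol=1e-15)
        np.testing.assert_allclose(v1v, 0.25, rtol=1e-12)

    def test_f_tyr_variance_toggle(self):
        args = (
            _trend(5.0, 0.0, 100.0),
            _trend(0.02, 0.0, 0.0),
            0.8,
            1e-4,
            10.0,
            0.0,
            GRID,
        )
        with_ft = flux_variances(*args, include_f_tyr_variance=True)
        without_ft = flux_variances(*args, include_f_tyr_variance=False)
        assert with_ft[1][-1] > 0.0
        np.testing.assert_array_equal(without_ft[1], 0.0)

    @pytest.mark.parametrize("balance", ["product_rule", "enrichment_only"])
    def test_agrees_with_monte_carlo_at_small_cv(self, balance):
        """Delta method vs 1e5-draw resample at ~2% CV on every input."""
        pool = _trend(5.0, (0.02 * 5.0) ** 2, 100.0)
        frac = _trend(0.02, (0.02 * 0.02) ** 2, 0.0)
        f_tyr, ft_var = 0.8, (0.02 * 0.8) ** 2
        vc, vc_var = 10.0, (0.02 * 10.0) ** 2
        ana_v1, ana_v2 = flux_variances(
            pool, frac, f_tyr, ft_var, vc, vc_var, GRID, balance=balance
        )
        mc_v1, mc_v2 = monte_carlo_flux_variance(
            pool, frac, f_tyr, ft_var, vc, vc_var, GRID,
            n_draws=100_000, seed=123, balance=balance,
        )
        np.testing.assert_allclose(mc_v1, ana_v1, rtol=0.05)
        np.testing.assert_allclose(mc_v2, ana_v2, rtol=0.05)
        # converged ratio band at CV = 2%
        assert np.all(mc_v2 / ana_v2 > 0.95) and np.all(mc_v2 / ana_v2 < 1.05)


class TestMonteCarlo:
    def test_zero_variances_give_zero_empirical_variance(self):
        v1v, v2v = monte_carlo_flux_variance(
            _trend(5.0, 0.0, 100.0), _trend(0.02, 0.0, 0.0), 0.8, 0.0, 10.0, 0.0,
            GRID, n_draws=500, seed=1,
        )
        np.testing.assert_allclose(v1v, 0.0, atol=1e-20)
        np.testing.assert_allclose(v2v, 0.0, atol=1e-20)

    def test_same_seed_is_deterministic(self):
        args = (
            _trend(5.0, 0.01, 100.0), _trend(0.02, 1e-6, 0.0), 0.8, 1e-4, 10.0, 0.04,
            GRID,
        )
        a = monte_carlo_flux_variance(*args, n_draws=1000, seed=99)
        b = monte_carlo_flux_variance(*args, n_draws=1000, seed=99)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError):
            monte_carlo_flux_variance(
                _trend(5.0, 0.0, 100.0), _trend(0.02, 0.0, 0.0), 0.8, 0.0, 10.0,
                0.0, GRID, n_draws=10,
            )
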