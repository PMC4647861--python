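"""Synthetic generator: determinism, oracles, genotype-pair construction."""

import numpy as np
import pytest

from phefluxes import (
    Perturbation,
    SyntheticScenario,
    compute_fluxes,
    make_genotype_pair,
    percent_change,
    run_pipeline,
    simulate_exact_linear,
    simulate_mechanistic,
)
from phefluxes.datamodel import AnalysisConfig, extract_series
from phefluxes.simulate import (
    InfeasibleScenarioError,
    ground_truth_fluxes,
    integrate_balances,
    perturb_scenario,
)
from phefluxes.datamodel import format_dataset


class TestExactLinear:
    def test_noise_free_pipeline_recovers_worked_fluxes(self):
        scenario = SyntheticScenario(
            pool_t0=100.0, pool_slope=5.0, frac_t0=0.0, frac_slope=0.02,
            f_tyr=0.8, v_c=10.0, cv_pool=0, cv_emission=0, sd_fraction=0,
        )
        ds, truth = simulate_exact_linear(scenario)
        mean = run_pipeline(ds).mean_trajectories["control"]
        assert mean.v2[0] == pytest.approx(2.5, abs=1e-9)
        assert mean.v2[-1] == pytest.approx(5.5, abs=1e-9)
        assert mean.v1[0] == pytest.approx(12.5, abs=1e-9)
        assert mean.v1[-1] == pytest.approx(9.5, abs=1e-9)
        np.testing.assert_allclose(mean.v1, truth.v1, rtol=1e-9)
        np.testing.assert_allclose(mean.v2, truth.v2, rtol=1e-9)

    def test_zero_label_slope_gives_zero_v2_truth(self):
        scenario = SyntheticScenario(frac_slope=0.0, frac_t0=0.0)
        truth = ground_truth_fluxes(scenario)
        np.testing.assert_array_equal(truth.v2, 0.0)

    def test_same_seed_gives_identical_bytes(self):
        a, _ = simulate_exact_linear(SyntheticScenario(seed=7))
        b, _ = simulate_exact_linear(SyntheticScenario(seed=7))
        assert format_dataset(a) == format_dataset(b)
        c, _ = simulate_exact_linear(SyntheticScenario(seed=8))
        assert format_dataset(a) != format_dataset(c)

    def test_infeasible_label_trajectory_rejected_before_generation(self):
        with pytest.raises(InfeasibleScenarioError):
            simulate_exact_linear(SyntheticScenario(frac_slope=0.2))

    def test_tyrosine_plateau_exceeds_80_percent(self):
        ds, _ = simulate_exact_linear(
            SyntheticScenario(cv_pool=0, cv_emission=0, sd_fraction=0)
        )
        _, f_tyr, _ = extract_series(ds, "control", "r1", "frac_tyr")
        assert np.all(f_tyr > 0.8)


class TestMechanistic:
    def test_integrator_matches_closed_form_exponential(self):
        """Constant fluxes v1=7.5, v2=2.5, vc=10, C0=100, f_Tyr=0.8:
        C stays at 100 and f(t) = 0.2(1 - exp(-0.1 t))."""
        scenario = SyntheticScenario(
            mode="mechanistic",
            v1_coeffs=(7.5, 0.0), v2_coeffs=(2.5, 0.0), v_c=10.0,
            pool_t0=100.0, frac_t0=0.0, f_tyr=0.8, f_tyr_rise_h=0.0,
            cv_pool=0, cv_emission=0, sd_fraction=0,
        )
        times, C, f = integrate_balances(scenario)
        np.testing.assert_allclose(C, 100.0, rtol=1e-10)
        expected = 0.2 * (1.0 - np.exp(-0.1 * times))
        assert abs(f[-1] - 0.2 * (1 - np.exp(-0.6))) <= 1e-8
        np.testing.assert_allclose(f, expected, atol=1e-8)

    def test_no_label_source_keeps_f_zero(self):
        scenario = SyntheticScenario(
            mode="mechanistic", v1_coeffs=(10.0, 0.0), v2_coeffs=(0.0, 0.0),
            v_c=5.0, frac_t0=0.0, cv_pool=0, cv_emission=0, sd_fraction=0,
        )
        _, _, f = integrate_balances(scenario)
        np.testing.assert_allclose(f, 0.0, atol=1e-14)

    def test_balanced_fluxes_keep_pool_constant(self):
        scenario = SyntheticScenario(
            mode="mechanistic", v1_coeffs=(4.0, 0.0), v2_coeffs=(6.0, 0.0),
            v_c=10.0, cv_pool=0, cv_emission=0, sd_fraction=0,
        )
        _, C, _ = integrate_balances(scenario)
        np.testing.assert_allclose(C, scenario.pool_t0, rtol=1e-10)

    def test_pool_exhaustion_is_an_error(self):
        scenario = SyntheticScenario(
            mode="mechanistic", pool_t0=5.0,
            v1_coeffs=(0.0, 0.0), v2_coeffs=(0.0, 0.0), v_c=10.0,
            cv_pool=0, cv_emission=0, sd_fraction=0,
        )
        with pytest.raises(InfeasibleScenarioError):
            integrate_balances(scenario)

    def test_dataset_mode_and_truth_fluxes(self):
        scenario = SyntheticScenario(
            mode="mechanistic", v1_coeffs=(12.0, -0.3), v2_coeffs=(1.0, 0.4),
            v_c=10.0, cv_pool=0, cv_emission=0, sd_fraction=0,
        )
        ds, truth = simulate_mechanistic(scenario)
        assert ds.metadata["mode"] == "mechanistic"
        np.testing.assert_allclose(truth.v1, 12.0 - 0.3 * truth.grid)
        np.testing.assert_allclose(truth.v2, 1.0 + 0.4 * truth.grid)


class TestGenotypePair:
    def test_identity_perturbation_shares_ground_truth(self):
        base = SyntheticScenario(cv_pool=0, cv_emission=0, sd_fraction=0)
        _, truths = make_genotype_pair(base, Perturbation())
        np.testing.assert_allclose(truths["control"].v1, truths["rnai"].v1)
        np.testing.assert_allclose(truths["control"].v2, truths["rnai"].v2)

    def test_v1_scaling_recovered_as_percent_change_at_t0(self):
        base = SyntheticScenario(cv_pool=0, cv_emission=0, sd_fraction=0)
        ds, truths = make_genotype_pair(base, Perturbation(v1_scale=0.6))
        config = AnalysisConfig(
            rnai_emission_fractions={"rnai": [1.0]}
        )
        means = run_pipeline(ds, config).mean_trajectories
        change = percent_change(float(means["control"].v1[0]), float(means["rnai"].v1[0]))
        assert change == pytest.approx(40.0, abs=1e-9)

    def test_v1_scaling_with_flat_v2_holds_at_all_times(self):
        # with no labelling trend v2 is constant, so the 40% drop in v1
        # propagates unchanged along the whole window
        base = SyntheticScenario(
            frac_slope=0.0, frac_t0=0.02, cv_pool=0, cv_emission=0, sd_fraction=0
        )
        _, truths = make_genotype_pair(base, Perturbation(v1_scale=0.6))
        np.testing.assert_allclose(
            truths["rnai"].v1, 0.6 * truths["control"].v1, rtol=1e-12
        )

    def test_vc_fraction_applied_by_construction(self):
        base = SyntheticScenario(cv_pool=0, cv_emission=0, sd_fraction=0)
        perturbed = perturb_scenario(base, Perturbation(vc_fraction=0.65))
        assert perturbed.v_c == pytest.approx(0.65 * base.v_c)

    def test_replicate_counts_and_determinism(self):
        base = SyntheticScenario(seed=3)
        ds1, _ = make_genotype_pair(base, perturbed_replicates=6)
        ds2, _ = make_genotype_pair(base, perturbed_replicates=6)
        assert format_dataset(ds1) == format_dataset(ds2)
        assert len(ds1.replicates("control")) == 3
        assert len(ds1.replicates("rnai")) == 6
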