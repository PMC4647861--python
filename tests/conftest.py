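import numpy as np
import pytest

from phefluxes import AnalysisConfig, SyntheticScenario
from phefluxes.simulate import simulate_exact_linear


@pytest.fixture
def noise_free_scenario() -> SyntheticScenario:
    return SyntheticScenario(cv_pool=0.0, cv_emission=0.0, sd_fraction=0.0)


@pytest.fixture
def noisy_scenario() -> SyntheticScenario:
    return SyntheticScenario(seed=42)


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


@pytest.fixture
def noise_free_dataset(noise_free_scenario):
    return simulate_exact_linear(noise_free_scenario)


def random_exact_linear_scenario(
    rng: np.random.Generator, noise: bool = False
) -> SyntheticScenario:
    """Feasible random scenario: f stays in [0, 1] and the pool positive."""
    return SyntheticScenario(
        pool_t0=rng.uniform(50.0, 200.0),
        pool_slope=rng.uniform(0.0, 10.0),
        frac_t0=rng.uniform(0.0, 0.05),
        frac_slope=rng.uniform(0.001, 0.02),
        f_tyr=rng.uniform(0.5, 0.95),
        v_c=rng.uniform(1.0, 20.0),
        cv_pool=0.05 if noise else 0.0,
        cv_emission=0.05 if noise else 0.0,
        sd_fraction=0.01 if noise else 0.0,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
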