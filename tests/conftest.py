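import numpy as np
import pytest

from secrsearch.model import ModelSpec
from secrsearch.sampler import SamplerConfig, run
from secrsearch.simulate import Scenario, simulate_scenario


def recovery_scenario(seed: int) -> Scenario:
    """Reserve-like scenario scaled for desk-speed parameter recovery."""
    return Scenario(area_km2=150.0, n_days=25, km_per_day=80.0, N_true=40,
                    prop_male_true=0.5, lambda0_true=0.01,
                    sigma_f_true=2.0, sigma_m_true=3.0,
                    point_spacing_km=0.2, seed=seed)


def tiny_scenario(seed: int = 3) -> Scenario:
    """Very small scenario for fast smoke-level fits."""
    return Scenario(area_km2=60.0, n_days=12, km_per_day=30.0, N_true=25,
                    prop_male_true=0.5, lambda0_true=0.02,
                    sigma_f_true=1.5, sigma_m_true=2.0,
                    point_spacing_km=0.25, seed=seed)


@pytest.fixture(scope="session")
def tiny_sim():
    return simulate_scenario(tiny_scenario())


@pytest.fixture(scope="session")
def recovery_sim():
    return simulate_scenario(recovery_scenario(7))


@pytest.fixture(scope="session")
def recovery_fit(recovery_sim):
    """One moderately long sex-specific-model fit, shared across tests."""
    cfg = SamplerConfig(n_iter=3000, burn_in=1000, n_chains=3, M=100, seed=11)
    return run(ModelSpec.from_id(1), recovery_sim["capture_history"],
               recovery_sim["effort"], recovery_sim["space"], cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
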