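import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from actitrial import DesignConfig, EffectScenario, simulate_trial

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def default_design():
    return DesignConfig()


@pytest.fixture
def null_scenario():
    """Treatment effect only: all nuisance effects zero."""
    return EffectScenario()


@pytest.fixture
def trial(default_design, null_scenario):
    return simulate_trial(default_design, null_scenario, seed=7)
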