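import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import dropqs as dq

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def config():
    """Default synthetic study conditions."""
    return dq.GeneratorConfig()


@pytest.fixture
def noiseless_config():
    """Generator with every noise source switched off (still stochastic in draws)."""
    return dq.GeneratorConfig(
        signal_noise_gsd=1.0, titration_noise_gsd=1.0, viable_fraction=1.0
    )


@pytest.fixture
def il10_curve(config):
    std = dq.generate_titration_standards(config, seed=11)
    return dq.fit_titration(std.query("cytokine == 'IL-10'"))
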