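import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

from phytocal.process_model import ModelConstants, ModelParams
from phytocal.synthetic_data import (
    SyntheticConfig,
    ToyConfig,
    generate_forcing,
    generate_toy_data,
)


@pytest.fixture(scope="session")
def constants():
    return ModelConstants()


@pytest.fixture(scope="session")
def forcing():
    """Default-season synthetic forcing, fixed seed."""
    return generate_forcing(SyntheticConfig(), seed=1)


@pytest.fixture(scope="session")
def quiet_forcing():
    """Noise-free forcing skeleton over a shorter span (fast tests)."""
    cfg = SyntheticConfig(
        end="2001-06-30", cloud_sigma=0.0, temp_noise=0.0, q_sigma=0.0, si_noise=0.0
    )
    return generate_forcing(cfg, seed=0)


@pytest.fixture(scope="session")
def toy_data():
    cfg = ToyConfig()
    t, y = generate_toy_data(cfg, seed=42)
    return cfg, t, y


@pytest.fixture()
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def mild_params():
    """Parameter draw that keeps silica positive (no state clipping)."""
    return ModelParams(1.2, 0.012, 42.0, 0.001, 0.15, 1.25)
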