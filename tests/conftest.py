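import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from divflow.core import SolverConfig
from divflow.synthetic import GridSpec, add_gaussian_noise, analytical_field

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def small_clean_stack():
    """Clean analytical 7-slice stack at reduced in-plane resolution."""
    return analytical_field(GridSpec(nx=48, ny=48, nz=7))


@pytest.fixture(scope="session")
def small_noisy_stack(small_clean_stack):
    return add_gaussian_noise(small_clean_stack, fraction=0.1, seed=11)


@pytest.fixture
def fast_config():
    return SolverConfig(gamma=150.0, lam=1.0, iterations=50, delta=1, region=40)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
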