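import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

from fltquant import PhantomSpec, generate_phantom


@pytest.fixture(scope="session")
def small_phantom():
    """Default 64^3 phantom (~11.7k tumor voxels), shared across read-only tests."""
    spec = PhantomSpec(seed=42)
    study, truth = generate_phantom(spec)
    return spec, study, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
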