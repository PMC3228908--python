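import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from aeiscope import synthetic_data as synth

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_refs():
    """Six random amplicon references (equal length so identity == Hamming)."""
    return synth.generate_reference(6, seed=11, length_range=(80, 80))


@pytest.fixture(scope="session")
def indices6():
    return synth.generate_indices(6, seed=11)
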