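import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "default",
    derandomize=True,
    database=None,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def constant(value):
    """A vectorized constant rate function of time."""
    v = float(value)
    return lambda t: np.full_like(np.asarray(t, dtype=float), v)


@pytest.fixture
def const_fn():
    return constant
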