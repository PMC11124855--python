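import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from myoreg.user import make_ideal_user

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
    return np.random.default_rng(12345)


@pytest.fixture
def ideal_user():
    """Noise-free, exactly decodable virtual user."""
    return make_ideal_user(seed=1)
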