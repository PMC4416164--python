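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


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_spec():
    from tfglasso.core import DynamicGraphSpec

    return DynamicGraphSpec(p=3, T=3, k=1)


def random_spd(d, rng, n_factor=3):
    A = rng.normal(size=(n_factor * d, d))
    return A.T @ A / (n_factor * d)
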