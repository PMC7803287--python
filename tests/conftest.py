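import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import conspicuity as cp

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def planted_weights():
    return (0.2, 0.1, 0.7)


@pytest.fixture(scope="session")
def bundle10(planted_weights):
    """10 labeled 128x128 scenes with an orientation-dominant planted mix."""
    return cp.make_synthetic_dataset(10, true_weights=planted_weights, seed=42)


@pytest.fixture(scope="session")
def texture_image():
    from conspicuity.synthetic import _random_texture

    return _random_texture((128, 128), seed=5)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
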