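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


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_positive_image(rng):
    """A small strictly positive test image."""
    return rng.uniform(10.0, 200.0, size=(24, 24))


@pytest.fixture(scope="session")
def standard_phantom():
    """The study phantom: 128x128, one disk, fully developed speckle."""
    from rdpad import Disk, make_phantom

    return make_phantom(
        128, 128,
        [Disk(cy=64, cx=64, r=30, level=200.0)],
        background=50.0,
        looks=1.0,
        seed=0,
    )
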