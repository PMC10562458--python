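import numpy as np
import pytest

from zfscreen import (
    HeartSimConfig,
    TrunkSimConfig,
    make_heart_movie,
    make_trunk_image,
)


@pytest.fixture(scope="session")
def default_heart_movie():
    """Noise-free 100-frame movie at 20 fps, 2 beats/s, true EF 50%."""
    return make_heart_movie(HeartSimConfig())


@pytest.fixture(scope="session")
def default_trunk():
    """Noise-free trunk projection with 12 ISV stripes."""
    return make_trunk_image(TrunkSimConfig())


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
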