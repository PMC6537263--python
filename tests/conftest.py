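import numpy as np
import pytest

from cvdenhance.colorspace import EncodedImage


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_image(rng):
    return EncodedImage(rng.random((32, 32, 3)))


def encoded(*rgb):
    """A 1x1 EncodedImage from a single RGB triple."""
    return EncodedImage(np.array(rgb, dtype=float).reshape(1, 1, 3))
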