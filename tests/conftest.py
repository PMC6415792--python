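import numpy as np
import pytest

from cytoorder.segmentation import BinaryMask


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_mask(rng, shape, p=0.3, pixel_size_nm=112.0):
    return BinaryMask(rng.random(shape) < p, pixel_size_nm)


@pytest.fixture
def bernoulli_mask(rng):
    return random_mask(rng, (24, 24), 0.3)
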