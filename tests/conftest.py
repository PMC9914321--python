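import numpy as np
import pytest

from mammofuse import GrayImage, PhantomSpec, generate_phantom, low_contrast_spec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_raw_image(rng):
    """A 16x16 raw 8-bit-scale image with full dynamic range."""
    return GrayImage(rng.uniform(0, 255, size=(16, 16)))


@pytest.fixture
def phantom32():
    img, ann = generate_phantom(PhantomSpec(height=32, width=32, seed=7))
    return img


@pytest.fixture
def low_contrast_phantom():
    img, ann = generate_phantom(low_contrast_spec(height=64, width=64, seed=11))
    return img
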