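import numpy as np
import pytest

from btseg import phantom


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture
def random_image(rng):
    """A 16x16 gray image with full 8-bit range."""
    return rng.integers(0, 256, size=(16, 16))


@pytest.fixture
def noiseless_phantom():
    spec = phantom.PhantomSpec(noise_sigma=0.0)
    img, mask, label = phantom.generate_phantom(spec)
    return img, mask, label
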