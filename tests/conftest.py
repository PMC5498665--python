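import numpy as np
import pytest

from neuroquant.micrograph import Micrograph


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def random_micrograph(rng):
    """A 64x64 16-bit image of uniform random intensities."""
    pix = rng.integers(0, 65536, size=(64, 64), dtype=np.uint16)
    return Micrograph(pixels=pix, bit_depth=16)
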