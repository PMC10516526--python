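import numpy as np
import pytest

from semrestore import ImageStack, make_phantom, make_textured_stack


@pytest.fixture(scope="session")
def phantom_small():
    """Default smooth-blob + bead phantom, 16 slices of 64x64."""
    return make_phantom((16, 64, 64), seed=5)


@pytest.fixture(scope="session")
def phantom_matrix():
    """Beadless (matrix-only) phantom: very smooth along z."""
    return make_phantom((16, 64, 64), seed=6, bead_fraction=0.0)


@pytest.fixture(scope="session")
def textured_slice():
    """A single sharp textured 128x128 slice for spectral tests."""
    return make_textured_stack(1, (128, 128), seed=3, texture_sigma=0.5).data[0]


@pytest.fixture
def rng():
    return np.random.default_rng(42)
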