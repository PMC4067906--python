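import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from stimchar.fixtures import ObjectSpec, generate_image
from stimchar.imageio_mask import compute_mask, to_grayscale


@pytest.fixture(scope="session")
def small_canvas() -> tuple[int, int]:
    """A reduced canvas so per-test image work stays fast."""
    return (120, 90)


@pytest.fixture
def black_square():
    """A centered 100 px black square on the standard 600x450 canvas."""
    img, truth = generate_image(ObjectSpec(shape="square", side_or_radius=100))
    return img, truth


@pytest.fixture
def gray_of():
    return to_grayscale


@pytest.fixture
def mask_of():
    return compute_mask


@pytest.fixture
def rng():
    return np.random.default_rng(20260925)
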