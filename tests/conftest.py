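import numpy as np
import pytest

from rtrecur import ImageVolume


def make_grid(shape=(40, 64, 64), spacing=(1.0, 1.0, 3.0)) -> ImageVolume:
    """Axis-aligned grid centered on the patient origin."""
    nz, ny, nx = shape
    sx, sy, sz = spacing
    origin = (-(nx - 1) * sx / 2, -(ny - 1) * sy / 2, -(nz - 1) * sz / 2)
    return ImageVolume(np.zeros(shape, dtype=np.float32), origin, spacing)


@pytest.fixture
def fine_grid():
    """Clinical-like 1 x 1 x 3 mm grid large enough for a 25 mm sphere."""
    return make_grid((40, 64, 64), (1.0, 1.0, 3.0))


@pytest.fixture
def coarse_grid():
    """2 x 2 x 3 mm grid for fast mask-level tests."""
    return make_grid((30, 48, 48), (2.0, 2.0, 3.0))
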