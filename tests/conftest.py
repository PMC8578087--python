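import numpy as np
import pytest

from vasculink.io_formats import BinaryMask, ImageVolume


@pytest.fixture
def small_volume() -> ImageVolume:
    rng = np.random.default_rng(42)
    vox = rng.integers(0, 255, size=(7, 6, 5), dtype=np.uint8)
    return ImageVolume(vox, spacing=(0.1, 0.2, 0.3), origin=(1.0, -2.0, 0.5))


@pytest.fixture
def small_mask() -> BinaryMask:
    vox = np.zeros((8, 8, 8), dtype=np.uint8)
    vox[2:6, 2:6, 2:6] = 1
    return BinaryMask(vox, spacing=(0.1, 0.1, 0.1))


def make_tube_mask(shape=(30, 9, 9), axis=0, radius_vox=2.0, spacing=0.1) -> BinaryMask:
    """Straight tube along ``axis`` through the grid center."""
    grids = np.meshgrid(*[np.arange(n, dtype=float) for n in shape], indexing="ij")
    center = [(n - 1) / 2 for n in shape]
    dist2 = sum(
        (grids[ax] - center[ax]) ** 2 for ax in range(3) if ax != axis
    )
    vox = (dist2 <= radius_vox**2).astype(np.uint8)
    return BinaryMask(vox, spacing=(spacing,) * 3)
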