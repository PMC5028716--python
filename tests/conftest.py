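import numpy as np
import pytest

from deltarad import ImageVolume, LesionMask


def make_ball_mask(radius_mm: float, spacing: float = 1.0, pad_mm: float = 3.0) -> LesionMask:
    """Digitized ball: voxel centers within radius_mm of the grid center."""
    n = int(2 * (radius_mm + pad_mm) / spacing) + 1
    ax = (np.arange(n) - (n - 1) / 2.0) * spacing
    z, y, x = np.meshgrid(ax, ax, ax, indexing="ij")
    data = (z**2 + y**2 + x**2 <= radius_mm**2).astype(np.uint8)
    return LesionMask(data=data, spacing=(spacing,) * 3)


def make_pair(data: np.ndarray, mask: np.ndarray, spacing=(1.0, 1.0, 1.0)):
    return (
        ImageVolume(data=np.asarray(data, dtype=float), spacing=spacing),
        LesionMask(data=np.asarray(mask, dtype=np.uint8), spacing=spacing),
    )


@pytest.fixture
def ball8():
    return make_ball_mask(8.0, spacing=1.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
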