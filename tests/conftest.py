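import numpy as np
import pytest

from ssfembed.logfilter import ScaleSpec


@pytest.fixture
def scales_2d():
    """Default radius sweep at isotropic 1 um voxels."""
    return ScaleSpec((4.0, 4.5, 5.0, 5.5, 6.0), (1.0, 1.0))


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def disk_image(size: int, radius: float, background: float = 1.0, disk: float = 0.0):
    """Dark disk on bright background, centered on the middle voxel."""
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[:size, :size]
    img = np.full((size, size), background, dtype=float)
    img[(yy - c) ** 2 + (xx - c) ** 2 <= radius**2] = disk
    return img, (int(c), int(c))
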