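import numpy as np
import pytest

from meningrad.features import DiscretizedVolume
from meningrad.imaging import SegmentationMask, VolumeImage


@pytest.fixture
def rng():
    return np.random.default_rng(20170908)


def random_discretized(rng, max_side=6, max_ng=4, full_mask=False) -> DiscretizedVolume:
    """Random small level grid (level 0 = background) for oracle comparisons."""
    shape = tuple(int(rng.integers(2, max_side + 1)) for _ in range(3))
    ng = int(rng.integers(2, max_ng + 1))
    levels = rng.integers(1, ng + 1, size=shape).astype(np.int32)
    if not full_mask:
        mask = rng.random(shape) < 0.8
        if mask.sum() < 2:
            mask.flat[:2] = True
        levels[~mask] = 0
    return DiscretizedVolume(
        levels=levels, ng=ng, bin_edges=np.arange(ng + 1, dtype=float), mask=levels > 0
    )


def digital_ball(radius_vox: int, spacing=1.0, pad: int = 3):
    """Binary ball mask on an isotropic grid."""
    n = 2 * (radius_vox + pad) + 1
    c = (n - 1) / 2
    x, y, z = np.ogrid[:n, :n, :n]
    ball = ((x - c) ** 2 + (y - c) ** 2 + (z - c) ** 2) <= radius_vox**2
    return SegmentationMask(ball.astype(np.uint8), spacing=(spacing,) * 3)


def volume_like(mask: SegmentationMask, values: np.ndarray) -> VolumeImage:
    return VolumeImage(values, spacing=mask.spacing, origin=mask.origin)
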