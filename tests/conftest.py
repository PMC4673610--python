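import numpy as np
import pytest
from skimage.draw import disk as draw_disk


def render_disks(centers, radii, shape):
    """Rasterize filled disks (float centers/radii) into a binary mask."""
    mask = np.zeros(shape, dtype=bool)
    for (cx, cy), r in zip(centers, radii):
        rr, cc = draw_disk((cy, cx), r, shape=shape)
        mask[rr, cc] = True
    return mask


def random_pattern(seed, shape=(512, 512), n=15, rmin=8, rmax=30, margin=60):
    """A reproducible multi-island binary pattern."""
    rng = np.random.default_rng(seed)
    h, w = shape
    centers = np.column_stack(
        [rng.uniform(margin, w - margin, n), rng.uniform(margin, h - margin, n)]
    )
    radii = rng.uniform(rmin, rmax, n)
    return render_disks(centers, radii, shape), centers, radii


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture
def pattern_512():
    mask, centers, radii = random_pattern(2)
    return mask


@pytest.fixture
def two_level_image():
    """Bright-field-like image: dark islands (40) on bright glass (200)."""
    mask, _, _ = random_pattern(7, shape=(256, 256), n=10, rmin=6, rmax=20)
    img = np.full((256, 256), 200, dtype=np.uint8)
    img[mask] = 40
    return img, mask
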