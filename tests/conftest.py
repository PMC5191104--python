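import numpy as np
import pytest

from jellyrec import imaging as im


@pytest.fixture
def square_scene():
    """64x64 dark field (20) with a 10x10 bright square (200) at [20:30, 25:35]."""
    img = np.full((64, 64), 20, np.uint8)
    img[20:30, 25:35] = 200
    return img


@pytest.fixture
def blurred_disk_scene():
    """Heavily smoothed bright disk: a blurred-particulate analogue."""
    from scipy import ndimage

    yy, xx = np.mgrid[0:96, 0:96]
    disk = ((yy - 48) ** 2 + (xx - 48) ** 2 <= 20**2).astype(float) * 180
    scene = 20 + ndimage.gaussian_filter(disk, 8)
    return np.clip(np.rint(scene), 0, 255).astype(np.uint8)


@pytest.fixture
def seg_cfg():
    """Raw-domain segmentation parameters used by the small clean fixtures."""
    return im.ImagingConfig(box_size=20, fg_threshold=10)


def blob_from_mask(mask):
    """Single blob from a boolean mask (test helper)."""
    pix = np.argwhere(mask)
    return im.Blob(pixels=pix, contour=im._inner_contour(mask))
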