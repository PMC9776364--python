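import numpy as np
import pytest
from skimage.draw import disk as draw_disk

from nucleiquant import NucleusMask


def disk_image(centers, radius, value=200, shape=(128, 128)):
    """Uint8 image with filled disks of a given intensity on black."""
    img = np.zeros(shape, dtype=np.uint8)
    for center in centers:
        rr, cc = draw_disk(center, radius, shape=shape)
        img[rr, cc] = value
    return img


def disk_area(radius, shape=(512, 512)):
    rr, _ = draw_disk((shape[0] // 2, shape[1] // 2), radius, shape=shape)
    return len(rr)


def make_mask(pixels, image=None, label_id=1, substack_index=0):
    """NucleusMask from an iterable of (row, col); intensities from image or 0."""
    pts = sorted(set(pixels))
    rows = np.array([p[0] for p in pts])
    cols = np.array([p[1] for p in pts])
    if image is None:
        size = max(rows.max(), cols.max()) + 1
        image = np.zeros((size, size), dtype=np.uint8)
    return NucleusMask.from_coords(label_id, rows, cols, image, substack_index)


@pytest.fixture
def two_disk_image():
    return disk_image([(30, 30), (90, 90)], radius=10)
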