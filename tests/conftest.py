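import numpy as np
import pytest
from scipy import ndimage

from chromatex.imaging import GrayImage, Mask, NucleusImage


def nucleus_from(pixels, mask=None, **meta) -> NucleusImage:
    """Build a NucleusImage from raw arrays (full mask by default)."""
    pixels = np.asarray(pixels)
    if mask is None:
        mask = np.ones(pixels.shape, dtype=bool)
    return NucleusImage(image=GrayImage(pixels), mask=Mask(mask), **meta)


def disk_mask(radius: int, pad: int = 2) -> np.ndarray:
    """Discrete disk: pixels whose centre lies within ``radius`` of the centre."""
    n = 2 * (radius + pad) + 1
    yy, xx = np.mgrid[:n, :n] - (radius + pad)
    return (yy**2 + xx**2) <= radius**2


def random_blob(rng, size: int = 20) -> np.ndarray:
    """A random single-component blob (largest component of smoothed noise)."""
    field = ndimage.gaussian_filter(rng.normal(size=(size, size)), sigma=2.5)
    mask = field > np.quantile(field, 0.6)
    lab, n = ndimage.label(mask, structure=np.ones((3, 3), dtype=bool))
    if n == 0:
        mask = np.zeros((size, size), dtype=bool)
        mask[size // 2, size // 2] = True
        return mask
    sizes = ndimage.sum_labels(mask, lab, index=range(1, n + 1))
    keep = int(np.argmax(sizes)) + 1
    filled = lab == keep
    return filled


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
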