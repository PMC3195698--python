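"""Loading and packaging of calibrated, masked nucleus images.

A nucleus is measured on an 8-bit grayscale image (0 = black, 255 = brightest)
restricted to a binary segmentation mask with exactly one 8-connected
foreground component.  RGB input is converted to luminance with ITU-R BT.601
weights; the conversion is exposed so callers can substitute another
convention.  The default pixel calibration is 0.1 um/pixel, the sample
spacing of high-power oil-immersion bone-marrow photomicrographs.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Optional

import imageio.v3 as iio
import numpy as np
from scipy import ndimage

from .errors import (
    DimensionError,
    EmptyMaskError,
    MultiComponentMaskError,
    UnsupportedFormatError,
)

#: ITU-R BT.601 luminance weights (R, G, B).
BT601_WEIGHTS = (0.299, 0.587, 0.114)

#: 8-connectivity structuring element for component labelling.
_STRUCT8 = np.ones((3, 3), dtype=bool)

CELL_CLASSES = ("blast", "atypical", "promyelocyte")


@dataclass(frozen=True)
class GrayImage:
    """8-bit grayscale image; 255 is the brightest level."""

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels)
        if px.ndim != 2:
            raise DimensionError(f"GrayImage needs a 2-D array, got shape {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("gray levels must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def height(self) -> int:
        return self.pixels.shape[0]

    @property
    def width(self) -> int:
        return self.pixels.shape[1]


@dataclass(frozen=True)
class Mask:
    """Binary nucleus mask: one 8-connected foreground component.

    Holes are allowed (they are simply excluded from the pixel set); a
    foreground that is empty or falls apart into several components is
    rejected, because every downstream feature assumes a single nucleus.
    """

    pixels: np.ndarray

    def __post_init__(self):
        px = np.asarray(self.pixels) > 0
        if px.ndim != 2:
            raise DimensionError(f"Mask needs a 2-D array, got shape {px.shape}")
        n_fg = int(px.sum())
        if n_fg == 0:
            raise EmptyMaskError("mask has no foreground pixel")
        _, n_comp = ndimage.label(px, structure=_STRUCT8)
        if n_comp != 1:
            raise MultiComponentMaskError(n_comp)
        object.__setattr__(self, "pixels", px)

    @property
    def n_foreground(self) -> int:
        return int(self.pixels.sum())


@dataclass(frozen=True)
class NucleusImage:
    """A calibrated, masked nucleus: the unit of measurement.

    ``pixel_size`` is the physical edge length of one pixel in micrometres.
    Downstream feature code only ever reads pixels inside the mask.
    """

    image: GrayImage
    mask: Mask
    pixel_size: float = 0.1
    patient_id: Optional[str] = None
    cell_class: Optional[str] = None
    cell_index: Optional[int] = None

    def __post_init__(self):
        if self.image.pixels.shape != self.mask.pixels.shape:
            raise DimensionError(
                f"image shape {self.image.pixels.shape} != mask shape "
                f"{self.mask.pixels.shape}"
            )
        if not self.pixel_size > 0:
            raise ValueError("pixel_size must be positive")
        if self.cell_class is not None and self.cell_class not in CELL_CLASSES:
            raise ValueError(
                f"cell_class must be one of {CELL_CLASSES}, got {self.cell_class!r}"
            )

    @property
    def masked_values(self) -> np.ndarray:
        """Gray values of the in-mask pixels, as a flat float array."""
        return self.image.pixels[self.mask.pixels].astype(float)


def to_grayscale(rgb: np.ndarray, weights=BT601_WEIGHTS) -> GrayImage:
    """Convert an 8-bit RGB array (H, W, 3) to luminance, rounding half up."""
    rgb = np.asarray(rgb, dtype=float)
    if rgb.ndim != 3 or rgb.shape[2] != 3:
        raise DimensionError(f"expected (H, W, 3) array, got shape {rgb.shape}")
    lum = rgb @ np.asarray(weights, dtype=float)
    lum = np.clip(np.floor(lum + 0.5), 0, 255)
    return GrayImage(lum)


def load_image(path) -> GrayImage:
    """Read an 8-bit gray or RGB image (BMP/PNG/TIFF) as a GrayImage."""
    if not os.path.exists(path):
        raise IOError(f"cannot read image file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:  # decoding failure
        raise IOError(f"cannot read image file: {path}") from exc
    if arr.dtype != np.uint8:
        raise UnsupportedFormatError(
            f"{path}: expected 8 bits per channel, got dtype {arr.dtype}"
        )
    if arr.ndim == 2:
        return GrayImage(arr)
    if arr.ndim == 3 and arr.shape[2] == 3:
        return to_grayscale(arr)
    raise UnsupportedFormatError(
        f"{path}: expected single-channel or RGB image, got shape {arr.shape}"
    )


def save_image(image: GrayImage, path) -> None:
    """Write a GrayImage losslessly (use PNG for a bit-exact round trip)."""
    iio.imwrite(path, image.pixels)


def load_mask(path) -> Mask:
    """Read a mask file; any pixel > 0 is foreground."""
    if not os.path.exists(path):
        raise IOError(f"cannot read mask file: {path}")
    try:
        arr = iio.imread(path)
    except Exception as exc:
        raise IOError(f"cannot read mask file: {path}") from exc
    if arr.ndim != 2:
        raise UnsupportedFormatError(
            f"{path}: mask must be single-channel, got shape {arr.shape}"
        )
    return Mask(arr > 0)


def make_nucleus(
    image: GrayImage,
    mask: Mask,
    pixel_size: float = 0.1,
    patient_id: Optional[str] = None,
    cell_class: Optional[str] = None,
    cell_index: Optional[int] = None,
) -> NucleusImage:
    """Bundle image + mask + calibration + metadata into a NucleusImage."""
    return NucleusImage(
        image=image,
        mask=mask,
        pixel_size=pixel_size,
        patient_id=patient_id,
        cell_class=cell_class,
        cell_index=cell_index,
    )
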