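"""Geometric and first-order gray-level descriptors of a segmented nucleus.

Conventions
-----------
* ``area_px`` counts foreground pixels; physical area is ``area_px * s**2``
  for pixel size ``s``.
* The perimeter is the length of the closed 8-connected chain traced through
  the centres of the outer boundary pixels (Moore neighbour tracing): each
  axial step contributes 1 pixel, each diagonal step sqrt(2).  An isolated
  pixel is assigned the boundary of its unit square, 4.0.  Hole boundaries
  are not counted.
* ``form_factor`` defaults to circularity 4*pi*A/P**2, clipped to <= 1
  (coarse discrete shapes can exceed 1; a 5x5 square gives a raw 1.227).
  The alternative ``axis_ratio`` is the minor/major axis ratio of the
  second-moment ellipse.
* Gray statistics are computed over in-mask pixels only; the standard
  deviation uses the sample convention (denominator n - 1).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from skimage.measure import regionprops

from .errors import ConfigurationError
from .imaging import NucleusImage

# Moore neighbourhood in clockwise order (row down the screen):
# E, SE, S, SW, W, NW, N, NE
_OFFS = [(0, 1), (1, 1), (1, 0), (1, -1), (0, -1), (-1, -1), (-1, 0), (-1, 1)]


@dataclass(frozen=True)
class MorphometryResult:
    area_px: int
    area_um2: float
    perimeter_px: float
    perimeter_um: float
    form_factor: float
    mean_gray: float
    sd_gray: float


def trace_boundary(mask: np.ndarray) -> list[tuple[int, int]]:
    """Trace the outer boundary of the foreground as a closed 8-connected chain.

    Moore neighbour tracing with Jacob's stopping criterion.  Returns the
    chain of boundary pixel coordinates; for multi-pixel regions the first
    pixel is repeated at the end so consecutive pairs enumerate every step
    of the closed walk.  For a single-pixel region the chain is just that
    pixel.
    """
    mask = np.asarray(mask) > 0
    h, w = mask.shape
    pts = np.argwhere(mask)
    if len(pts) == 0:
        raise ValueError("empty mask")
    start = (int(pts[0][0]), int(pts[0][1]))  # topmost, then leftmost

    def fg(r, c):
        return 0 <= r < h and 0 <= c < w and mask[r, c]

    if not any(fg(start[0] + dr, start[1] + dc) for dr, dc in _OFFS):
        return [start]

    chain = [start]
    p = start
    b_idx = 4  # backtrack: the (background) pixel west of the start
    first_next = None
    while True:
        for k in range(1, 9):
            idx = (b_idx + k) % 8
            n = (p[0] + _OFFS[idx][0], p[1] + _OFFS[idx][1])
            if fg(*n):
                break
        if first_next is None:
            first_next = n
        elif p == start and n == first_next:
            break
        prev_idx = (idx - 1) % 8
        back = (
            p[0] + _OFFS[prev_idx][0] - n[0],
            p[1] + _OFFS[prev_idx][1] - n[1],
        )
        chain.append(n)
        b_idx = _OFFS.index(back)
        p = n
    return chain


def chain_length(chain: list[tuple[int, int]]) -> float:
    """Length of a pixel chain: axial steps count 1, diagonal steps sqrt(2)."""
    if len(chain) == 1:
        return 4.0  # unit-square boundary of an isolated pixel
    total = 0.0
    for (r0, c0), (r1, c1) in zip(chain[:-1], chain[1:]):
        total += math.sqrt((r1 - r0) ** 2 + (c1 - c0) ** 2)
    return total


def area(nucleus: NucleusImage) -> tuple[int, float]:
    """Foreground pixel count and calibrated area in um^2."""
    n = nucleus.mask.n_foreground
    return n, n * nucleus.pixel_size**2


def perimeter(nucleus: NucleusImage) -> tuple[float, float]:
    """Outer boundary length in pixel units and in micrometres."""
    p = chain_length(trace_boundary(nucleus.mask.pixels))
    return p, p * nucleus.pixel_size


def form_factor(nucleus: NucleusImage, method: str = "circularity") -> float:
    if method == "circularity":
        a, _ = area(nucleus)
        p, _ = perimeter(nucleus)
        return min(1.0, 4.0 * math.pi * a / p**2)
    if method == "axis_ratio":
        props = regionprops(nucleus.mask.pixels.astype(np.uint8))[0]
        major = props.axis_major_length
        minor = props.axis_minor_length
        if major == 0:  # single pixel / degenerate
            return 1.0
        return minor / major
    raise ConfigurationError(f"unknown form-factor method: {method!r}")


def gray_stats(nucleus: NucleusImage) -> tuple[float, float]:
    """Mean and sample SD (n-1) of gray values over in-mask pixels."""
    vals = nucleus.masked_values
    mean = float(vals.mean())
    if vals.size < 2:
        warnings.warn("single-pixel mask: sd_gray reported as 0", stacklevel=2)
        return mean, 0.0
    return mean, float(vals.std(ddof=1))


def morphometry(nucleus: NucleusImage, ff_method: str = "circularity") -> MorphometryResult:
    """All first-order descriptors of one nucleus."""
    area_px, area_um2 = area(nucleus)
    per_px, per_um = perimeter(nucleus)
    mean_gray, sd_gray = gray_stats(nucleus)
    return MorphometryResult(
        area_px=area_px,
        area_um2=area_um2,
        perimeter_px=per_px,
        perimeter_um=per_um,
        form_factor=form_factor(nucleus, ff_method),
        mean_gray=mean_gray,
        sd_gray=sd_gray,
    )
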