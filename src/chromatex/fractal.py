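"""Minkowski-Bouligand fractal dimension of the pseudo-3D intensity surface.

The gray-level image is treated as a surface (height = gray value).  The
morphological *blanket* method grows an upper envelope ``u`` and a lower
envelope ``l`` around the surface: starting from u_0 = l_0 = g,

    u_e(x) = max( u_{e-1}(x) + 1,  max over neighbours of u_{e-1} )
    l_e(x) = min( l_{e-1}(x) - 1,  min over neighbours of l_{e-1} )

with the neighbourhood a flat 3x3 structuring element (8-neighbourhood;
a 4-neighbourhood cross is available).  Only in-mask pixels evolve, and
neighbours outside the mask are ignored, so the estimate is intrinsic to
the segmented nucleus.  The blanket volume

    V(e) = sum over mask of (u_e - l_e)

scales as e^(3 - FD) for a fractal surface; ordinary least squares on
log V(e) vs log e gives FD = 3 - slope, and the regression R^2 is itself
reported as a texture feature (rough, non-fractal surfaces break the
power law and lower R^2).

A perfectly flat surface yields V(e) = 2 e N exactly, hence FD = 2 and
R^2 = 1: the plane limit.  FD estimates outside [2, 3] (with 0.05
tolerance) are flagged, not clipped.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
from scipy import ndimage, stats

from .errors import ConfigurationError, DegenerateFitError
from .imaging import NucleusImage

_FOOTPRINTS = {
    8: np.ones((3, 3), dtype=bool),
    4: np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool),
}


@dataclass(frozen=True)
class BlanketSeries:
    epsilons: np.ndarray  # dilation radii 1..eps_max
    volumes: np.ndarray  # V(eps), strictly increasing
    n_mask_pixels: int


@dataclass(frozen=True)
class FractalFit:
    fd: float
    r2: float
    slope: float
    intercept: float
    fit_range: tuple  # epsilon values used
    flagged: bool  # fd outside [2 - 0.05, 3 + 0.05]


def blanket_volumes(
    surface: np.ndarray,
    mask: Optional[np.ndarray] = None,
    eps_max: int = 10,
    neighborhood: int = 8,
) -> BlanketSeries:
    """Blanket-volume series of an arbitrary (float) surface under a mask."""
    if eps_max < 3:
        raise ConfigurationError("eps_max must be >= 3 (the fit needs >= 3 points)")
    if neighborhood not in _FOOTPRINTS:
        raise ConfigurationError("neighborhood must be 4 or 8")
    surface = np.asarray(surface, dtype=float)
    if mask is None:
        mask = np.ones(surface.shape, dtype=bool)
    mask = np.asarray(mask) > 0
    n = int(mask.sum())
    if n < 9:
        raise ConfigurationError("mask must contain at least 9 pixels")
    foot = _FOOTPRINTS[neighborhood]

    u = np.where(mask, surface, -np.inf)
    low = np.where(mask, surface, np.inf)
    volumes = np.empty(eps_max, dtype=float)
    for e in range(1, eps_max + 1):
        dil = ndimage.maximum_filter(u, footprint=foot, mode="constant", cval=-np.inf)
        ero = ndimage.minimum_filter(low, footprint=foot, mode="constant", cval=np.inf)
        u = np.where(mask, np.maximum(u + 1.0, dil), -np.inf)
        low = np.where(mask, np.minimum(low - 1.0, ero), np.inf)
        volumes[e - 1] = float((u - low)[mask].sum())
    return BlanketSeries(
        epsilons=np.arange(1, eps_max + 1), volumes=volumes, n_mask_pixels=n
    )


def blanket_transform(
    nucleus: NucleusImage, eps_max: int = 10, neighborhood: int = 8
) -> BlanketSeries:
    """Blanket-volume series of a nucleus's gray-level surface."""
    return blanket_volumes(
        nucleus.image.pixels.astype(float),
        nucleus.mask.pixels,
        eps_max=eps_max,
        neighborhood=neighborhood,
    )


def minkowski_fd(
    series: BlanketSeries, fit_range: Optional[Sequence[int]] = None
) -> FractalFit:
    """OLS fit of log V(eps) on log eps; FD = 3 - slope.

    ``fit_range`` selects epsilon values (not indices); default: all.
    """
    eps = np.asarray(series.epsilons, dtype=float)
    vol = np.asarray(series.volumes, dtype=float)
    if fit_range is not None:
        sel = np.isin(series.epsilons, np.asarray(fit_range))
        eps, vol = eps[sel], vol[sel]
    if eps.size < 3:
        raise ConfigurationError("fit needs at least 3 (eps, V) points")
    x = np.log(eps)
    if np.ptp(x) == 0:
        raise DegenerateFitError("zero variance in log(eps)")
    y = np.log(vol)
    res = stats.linregress(x, y)
    fd = 3.0 - res.slope
    return FractalFit(
        fd=fd,
        r2=float(res.rvalue**2),
        slope=float(res.slope),
        intercept=float(res.intercept),
        fit_range=tuple(int(e) for e in eps),
        flagged=not (2.0 - 0.05 <= fd <= 3.0 + 0.05),
    )


def fractal_dimension(
    nucleus: NucleusImage, eps_max: int = 10, neighborhood: int = 8
) -> FractalFit:
    """Convenience wrapper: blanket series + log-log fit in one call."""
    return minkowski_fd(blanket_transform(nucleus, eps_max, neighborhood))
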