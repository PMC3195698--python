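"""Gray-level co-occurrence matrix (GLCM) and the derived texture features.

The matrix is built over in-mask pixel pairs only: a pair contributes iff
both pixels lie inside the nucleus mask.  Pairs are accumulated over the
four standard directions (0, 45, 90, 135 degrees) in both orientations, so
the matrix is symmetric and a single value per feature summarises the
nucleus — matching how karyometry studies report one number per cell.

Feature formulas, with p(i, j) the normalised matrix and
mu_x = sum_i i p(i,j), mu_y = sum_j j p(i,j):

* entropy            -sum p log2 p            (bits; 0 log 0 := 0)
* inertia = contrast  sum (i-j)^2 p           (two names, one quantity)
* local_homogeneity   sum p / (1 + (i-j)^2)
* energy_normalized   sum p^2                 (angular second moment)
* energy_raw          sum counts^2            (unnormalised variant)
* diagonal_moment     sum |i-j| p             (difference first moment)
* cluster_prominence  sum (i+j-mu_x-mu_y)^4 p

"Inertia" and "contrast" are deliberately exposed as two fields with
identical values, and "diagonal moment" is the absolute-difference first
moment (also known as dissimilarity): neither has a single canonical
definition in the karyometry literature, so the choice is made explicit
here and both energies are reported.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError, DegenerateMatrixError
from .imaging import NucleusImage

#: Offsets (drow, dcol) for 0, 45, 90, 135 degrees at unit distance.
DIRECTIONS_4 = ((0, 1), (-1, 1), (-1, 0), (-1, -1))

_VALID_LEVELS = (16, 32, 64, 128, 256)


@dataclass(frozen=True)
class CooccurrenceMatrix:
    counts: np.ndarray  # G x G symmetric pair counts
    probs: np.ndarray  # counts / total, sums to 1
    levels: int
    distance: int
    directions: tuple


@dataclass(frozen=True)
class GLCMFeatureSet:
    entropy: float
    inertia: float
    local_homogeneity: float
    energy_normalized: float
    energy_raw: float
    contrast: float
    diagonal_moment: float
    cluster_prominence: float
    mu_x: float
    mu_y: float


def quantize(gray: np.ndarray, levels: int) -> np.ndarray:
    """Map 8-bit gray values onto ``levels`` equal-width bins."""
    return (gray.astype(np.int64) * levels) // 256


def build_glcm(
    nucleus: NucleusImage,
    distance: int = 1,
    directions=DIRECTIONS_4,
    levels: int = 256,
) -> CooccurrenceMatrix:
    """Accumulate the symmetric co-occurrence matrix over in-mask pairs."""
    if levels not in _VALID_LEVELS:
        raise ConfigurationError(f"levels must be one of {_VALID_LEVELS}, got {levels}")
    if distance < 1:
        raise ConfigurationError("distance must be >= 1")
    mask = nucleus.mask.pixels
    q = quantize(nucleus.image.pixels, levels)
    counts = np.zeros((levels, levels), dtype=np.int64)
    h, w = mask.shape
    for dr, dc in directions:
        dr, dc = dr * distance, dc * distance
        r0, r1 = max(0, -dr), min(h, h - dr)
        c0, c1 = max(0, -dc), min(w, w - dc)
        if r0 >= r1 or c0 >= c1:
            continue
        valid = mask[r0:r1, c0:c1] & mask[r0 + dr : r1 + dr, c0 + dc : c1 + dc]
        a = q[r0:r1, c0:c1][valid]
        b = q[r0 + dr : r1 + dr, c0 + dc : c1 + dc][valid]
        np.add.at(counts, (a, b), 1)
        np.add.at(counts, (b, a), 1)
    total = counts.sum()
    if total == 0:
        raise DegenerateMatrixError(
            f"no in-mask pixel pair at distance {distance} in any direction"
        )
    return CooccurrenceMatrix(
        counts=counts,
        probs=counts / total,
        levels=levels,
        distance=distance,
        directions=tuple(directions),
    )


def glcm_features(m: CooccurrenceMatrix) -> GLCMFeatureSet:
    """The seven texture features (plus the raw-energy variant)."""
    p = m.probs
    g = m.levels
    i = np.arange(g, dtype=float)[:, None]
    j = np.arange(g, dtype=float)[None, :]
    diff = i - j

    nz = p[p > 0]
    entropy = float(-(nz * np.log2(nz)).sum())
    inertia = float(((diff**2) * p).sum())
    local_homogeneity = float((p / (1.0 + diff**2)).sum())
    energy_normalized = float((p**2).sum())
    energy_raw = float((m.counts.astype(float) ** 2).sum())
    diagonal_moment = float((np.abs(diff) * p).sum())
    mu_x = float((i * p).sum())
    mu_y = float((j * p).sum())
    cluster_prominence = float((((i + j - mu_x - mu_y) ** 4) * p).sum())
    return GLCMFeatureSet(
        entropy=entropy,
        inertia=inertia,
        local_homogeneity=local_homogeneity,
        energy_normalized=energy_normalized,
        energy_raw=energy_raw,
        contrast=inertia,
        diagonal_moment=diagonal_moment,
        cluster_prominence=cluster_prominence,
        mu_x=mu_x,
        mu_y=mu_y,
    )
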