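"""Synthetic nuclei and cohorts with known ground truth.

Two generators stand in for stained bone-marrow smears, which cannot be
redistributed:

* **Nucleus images** — a roughly elliptical mask (low-order Fourier
  perturbation of an ellipse, ~100-120 um^2 at 0.1 um/pixel) filled with a
  fractional-Brownian-motion (fBm) texture of Hurst exponent H (theoretical
  surface dimension FD = 3 - H), plus Gaussian "chromatin clump" darkening,
  affinely rescaled to a target in-mask mean and SD.  Roughness (H), clump
  structure and boundary irregularity are the ground-truth dials.

* **Feature cohorts** — per-patient, per-class feature means drawn from a
  mixed model: class mean + patient random effect (variance rho*sigma^2)
  + residual (variance (1-rho)*sigma^2).  The atypical class mean is the
  mixture lambda*mu_blast + (1-lambda)*mu_promyelocyte, so lambda encodes
  where the atypical precursor sits on the blast->promyelocyte axis
  (lambda=1: pure blast; 0: pure promyelocyte; 0.5: halfway).

Everything is a pure function of (recipe, seed).  fBm is synthesised
spectrally (power spectrum ~ f^-(2H+2)), which gives exact stationarity
control; the surface is returned normalised and callers choose amplitude.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Dict, Optional, Tuple

import numpy as np
import pandas as pd
from scipy import ndimage

from .errors import ChromatexError
from .imaging import GrayImage, Mask, NucleusImage

#: Feature names produced by the extraction pipeline, in reporting order.
FEATURE_NAMES = (
    "area_um2",
    "perimeter_px",
    "form_factor",
    "mean_gray",
    "sd_gray",
    "entropy",
    "inertia",
    "local_homogeneity",
    "energy_raw",
    "contrast",
    "diagonal_moment",
    "cluster_prominence",
    "fd_minkowski",
    "fd_r2",
)


# --------------------------------------------------------------------------
# fBm surfaces
# --------------------------------------------------------------------------

def fbm_surface(
    shape: Tuple[int, int],
    hurst: float,
    rng: np.random.Generator,
    oversample: int = 2,
) -> np.ndarray:
    """Fractional-Brownian surface by spectral synthesis, zero mean, unit SD.

    The amplitude spectrum is |f|^-(H+1) (power ~ f^-(2H+2)); phases come
    from complex Gaussian white noise, so the field is stationary and
    isotropic up to the square lattice.

    Synthesis at the target resolution is band-limited at the Nyquist
    frequency, which makes the surface unrealistically smooth at the
    1-2 pixel scale and biases blanket dimension estimates.  The field is
    therefore synthesised on an ``oversample``-times finer grid and
    decimated, which folds the sub-pixel power back into the samples the
    way point-sampling of a true fBm surface would.
    """
    if not 0.0 < hurst < 1.0:
        raise ValueError("hurst must be in (0, 1)")
    if oversample < 1:
        raise ValueError("oversample must be >= 1")
    h, w = shape[0] * oversample, shape[1] * oversample
    fy = np.fft.fftfreq(h)[:, None]
    fx = np.fft.fftfreq(w)[None, :]
    f = np.hypot(fy, fx)
    amp = np.zeros_like(f)
    nzero = f > 0
    amp[nzero] = f[nzero] ** -(hurst + 1.0)
    noise = rng.normal(size=(h, w)) + 1j * rng.normal(size=(h, w))
    field = np.fft.ifft2(noise * amp).real[::oversample, ::oversample]
    field -= field.mean()
    sd = field.std()
    if sd > 0:
        field /= sd
    return field


def scale_to_increment_rms(field: np.ndarray, increment_rms: float) -> np.ndarray:
    """Rescale a surface so adjacent-pixel height differences have a given RMS.

    The blanket estimator is not amplitude-invariant on a discrete lattice
    (its +-1 vertical step sets an absolute scale), so fractal-recovery
    experiments fix the local relief amplitude rather than the global SD.
    """
    dv = np.diff(field, axis=0).ravel()
    dh = np.diff(field, axis=1).ravel()
    rms = math.sqrt(float(np.mean(np.concatenate([dv, dh]) ** 2)))
    if rms == 0:
        return field.copy()
    return field * (increment_rms / rms)


# --------------------------------------------------------------------------
# Nucleus images
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class NucleusRecipe:
    """Ground-truth parameters of one synthetic nucleus.

    ``mask_area_px`` defaults to ~115 um^2 at 0.1 um/pixel.  H controls
    texture roughness (FD = 3 - H); clumps add dark Gaussian blobs of
    amplitude ``clump_amplitude`` gray levels (before rescaling) and radius
    ``clump_sigma`` pixels.  ``boundary_irregularity`` is the relative
    amplitude of the low-order Fourier perturbation of the elliptical
    outline; 0 gives an exact (discrete) ellipse.
    """

    mask_area_px: int = 11500
    boundary_irregularity: float = 0.03
    axis_ratio: float = 0.9
    hurst: float = 0.45
    clump_count: int = 8
    clump_amplitude: float = 20.0
    clump_sigma: float = 6.0
    target_mean_gray: float = 123.0
    target_sd_gray: float = 8.5

    def __post_init__(self):
        if not 0.0 < self.hurst < 1.0:
            raise ValueError("hurst must be in (0, 1)")
        if self.boundary_irregularity < 0 or self.clump_amplitude < 0:
            raise ValueError("amplitudes must be >= 0")
        if not 0 < self.axis_ratio <= 1:
            raise ValueError("axis_ratio must be in (0, 1]")
        if self.mask_area_px < 50:
            raise ValueError("mask_area_px must be >= 50")


#: Parameter directions follow the blast-vs-promyelocyte contrast seen in
#: normal marrow: promyelocytes have larger, more indented nuclei with
#: smoother, more homogeneous (lower-entropy, lower-FD) chromatin.
BLAST_LIKE = NucleusRecipe(
    mask_area_px=11800,
    boundary_irregularity=0.015,
    axis_ratio=0.95,
    hurst=0.35,
    clump_count=10,
    clump_amplitude=22.0,
    clump_sigma=5.0,
    target_mean_gray=125.0,
    target_sd_gray=9.1,
)

PROMYELOCYTE_LIKE = NucleusRecipe(
    mask_area_px=12100,
    boundary_irregularity=0.10,
    axis_ratio=0.78,
    hurst=0.60,
    clump_count=5,
    clump_amplitude=14.0,
    clump_sigma=8.0,
    target_mean_gray=118.6,
    target_sd_gray=8.1,
)

PRESETS = {"blast_like": BLAST_LIKE, "promyelocyte_like": PROMYELOCYTE_LIKE}


def blend_recipes(lam: float, blast: NucleusRecipe = BLAST_LIKE,
                  pro: NucleusRecipe = PROMYELOCYTE_LIKE) -> NucleusRecipe:
    """Interpolate texture parameters: lam=1 -> blast-like, 0 -> promyelocyte-like."""
    mix = lambda a, b: lam * a + (1.0 - lam) * b
    return NucleusRecipe(
        mask_area_px=int(round(mix(blast.mask_area_px, pro.mask_area_px))),
        boundary_irregularity=mix(blast.boundary_irregularity, pro.boundary_irregularity),
        axis_ratio=mix(blast.axis_ratio, pro.axis_ratio),
        hurst=mix(blast.hurst, pro.hurst),
        clump_count=int(round(mix(blast.clump_count, pro.clump_count))),
        clump_amplitude=mix(blast.clump_amplitude, pro.clump_amplitude),
        clump_sigma=mix(blast.clump_sigma, pro.clump_sigma),
        target_mean_gray=mix(blast.target_mean_gray, pro.target_mean_gray),
        target_sd_gray=mix(blast.target_sd_gray, pro.target_sd_gray),
    )


def generate_mask(recipe: NucleusRecipe, seed) -> Mask:
    """Rasterise a Fourier-perturbed ellipse of the target area.

    Retries (fresh harmonics) up to 10 times if the perturbation splits the
    region or the area misses the target by more than 10%.
    """
    rng = np.random.default_rng(seed)
    target = recipe.mask_area_px
    for _ in range(10):
        # ellipse semi-axes with the requested area and axis ratio
        a = math.sqrt(target / (math.pi * recipe.axis_ratio))
        b = a * recipe.axis_ratio
        # low-order harmonics of the outline radius
        ks = np.arange(2, 6)
        amps = recipe.boundary_irregularity * rng.uniform(0.4, 1.0, size=ks.size)
        phases = rng.uniform(0, 2 * math.pi, size=ks.size)
        theta_rot = rng.uniform(0, math.pi)

        half = int(math.ceil(a * (1 + recipe.boundary_irregularity * 4) + 2))
        yy, xx = np.mgrid[-half : half + 1, -half : half + 1].astype(float)
        ct, st = math.cos(theta_rot), math.sin(theta_rot)
        xr = ct * xx + st * yy
        yr = -st * xx + ct * yy
        rho = np.hypot(xr / a, yr / b)
        theta = np.arctan2(yr / b, xr / a)
        bound = 1.0 + sum(
            amp * np.cos(k * theta + ph) for k, amp, ph in zip(ks, amps, phases)
        )
        px = rho <= bound
        n = int(px.sum())
        if n == 0:
            continue
        # one corrective rescale toward the target area
        scale = math.sqrt(target / n)
        rho2 = np.hypot(xr / (a * scale), yr / (b * scale))
        px = rho2 <= bound
        n = int(px.sum())
        if abs(n - target) / target > 0.10:
            continue
        lab, n_comp = ndimage.label(px, structure=np.ones((3, 3), dtype=bool))
        if n_comp != 1:
            continue
        return Mask(px)
    raise ChromatexError(
        "could not generate a single-component mask within 10 attempts "
        f"(irregularity={recipe.boundary_irregularity})"
    )


def generate_texture(recipe: NucleusRecipe, mask: Mask, seed) -> GrayImage:
    """Fill a mask with fBm + clump texture at the target mean/SD.

    The raw field is ``target_sd * fBm - sum of Gaussian clumps`` (clumps
    darken, as condensed chromatin does), then affinely rescaled so the
    in-mask mean and SD hit their targets before clipping to [0, 255].
    If clipping distorts the achieved moments beyond +-2 (mean) / +-1 (SD),
    a warning reports the achieved values.
    """
    rng = np.random.default_rng(seed)
    mpx = mask.pixels
    h, w = mpx.shape
    field = recipe.target_sd_gray * fbm_surface((h, w), recipe.hurst, rng)

    if recipe.clump_count > 0 and recipe.clump_amplitude > 0:
        fg = np.argwhere(mpx)
        centers = fg[rng.integers(0, len(fg), size=recipe.clump_count)]
        yy, xx = np.mgrid[0:h, 0:w].astype(float)
        for (cy, cx) in centers:
            d2 = (yy - cy) ** 2 + (xx - cx) ** 2
            field -= recipe.clump_amplitude * np.exp(-d2 / (2 * recipe.clump_sigma**2))

    vals = field[mpx]
    mu, sd = vals.mean(), vals.std()
    if sd > 0 and recipe.target_sd_gray > 0:
        field = (field - mu) * (recipe.target_sd_gray / sd) + recipe.target_mean_gray
    else:
        field = field - mu + recipe.target_mean_gray
    pixels = np.clip(np.floor(field + 0.5), 0, 255)
    pixels[~mpx] = 255  # bright smear background; never read downstream

    got = pixels[mpx]
    got_mu, got_sd = float(got.mean()), float(got.std())
    if abs(got_mu - recipe.target_mean_gray) > 2.0 or abs(got_sd - recipe.target_sd_gray) > 1.0:
        warnings.warn(
            f"clipping distorted texture moments: mean {got_mu:.1f} "
            f"(target {recipe.target_mean_gray}), sd {got_sd:.2f} "
            f"(target {recipe.target_sd_gray})",
            stacklevel=2,
        )
    return GrayImage(pixels)


def generate_nucleus(
    recipe: NucleusRecipe,
    seed,
    pixel_size: float = 0.1,
    patient_id: Optional[str] = None,
    cell_class: Optional[str] = None,
    cell_index: Optional[int] = None,
) -> NucleusImage:
    """Mask + texture in one call; sub-seeds are split deterministically."""
    if not isinstance(seed, np.random.SeedSequence):
        seed = np.random.SeedSequence(seed)
    ss = seed.spawn(2)
    mask = generate_mask(recipe, ss[0])
    image = generate_texture(recipe, mask, ss[1])
    return NucleusImage(
        image=image,
        mask=mask,
        pixel_size=pixel_size,
        patient_id=patient_id,
        cell_class=cell_class,
        cell_index=cell_index,
    )


# --------------------------------------------------------------------------
# Feature-level cohorts
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class CohortRecipe:
    """Mixed-model recipe for per-patient, per-class feature means.

    ``features`` maps a feature name to (mu_blast, mu_promyelocyte, sd);
    the atypical mean is lam*mu_blast + (1-lam)*mu_promyelocyte.  ``rho``
    splits the variance sd^2 into a shared patient effect (rho*sd^2) and an
    independent residual.  Defaults mirror the study conditions: 30 MDS
    patients, >= 30 nuclei per class, and class means taken from reported
    MDS blast/promyelocyte values with SDs set to half the class gap
    (a 2-SD separation) for the features that differ.
    """

    n_patients: int = 30
    n_nuclei_per_class: int = 30
    features: Dict[str, Tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_FEATURE_PARAMS)
    )
    lam: float = 0.5
    rho: float = 0.5
    cohort: str = "MDS"

    def __post_init__(self):
        if not 0.0 <= self.lam <= 1.0:
            raise ValueError("lam must be in [0, 1]")
        if not 0.0 <= self.rho < 1.0:
            raise ValueError("rho must be in [0, 1)")
        for name, (mb, mp, sd) in self.features.items():
            if sd <= 0:
                raise ValueError(f"sd must be > 0 (feature {name})")


def _default_feature_params() -> Dict[str, Tuple[float, float, float]]:
    # (mu_blast, mu_promyelocyte, sd); sd = |gap| / 2 where the classes
    # differ, otherwise a small fraction of the common mean.
    published = {
        "area_um2": (118.4, 121.0),
        "perimeter_px": (598.0, 656.0),
        "form_factor": (0.94, 0.80),
        "mean_gray": (125.1, 118.6),
        "sd_gray": (9.1, 8.1),
        "entropy": (7.65, 7.52),
        "inertia": (3.67, 3.28),
        "local_homogeneity": (0.553, 0.558),
        "energy_raw": (6749.0, 5595.0),
        "contrast": (3.67, 3.28),
        "diagonal_moment": (17.4, 15.6),
        "cluster_prominence": (3.17, 2.19),
        "fd_minkowski": (2.1225, 2.1180),
        "fd_r2": (0.99819, 0.99809),
    }
    out = {}
    for name, (mb, mp) in published.items():
        gap = abs(mb - mp)
        sd = gap / 2.0 if gap > 0 else 0.02 * abs(mb)
        out[name] = (mb, mp, sd)
    return out


DEFAULT_FEATURE_PARAMS = _default_feature_params()


def expected_label(mu_blast: float, mu_pro: float, lam: float) -> str:
    """Ground-truth label implied by the mixing weight and class gap."""
    if mu_blast == mu_pro:
        return "not_defined"
    if lam == 1.0:
        return "close_to_blasts"
    if lam == 0.0:
        return "close_to_promyelocytes"
    return "intermediate"


def simulate_cohort(recipe: CohortRecipe, seed) -> Tuple[pd.DataFrame, pd.DataFrame]:
    """Draw per-patient, per-class feature means and their ground truth.

    Returns ``(table, truth)``: ``table`` has one row per (patient, class)
    with one column per feature plus ``n_nuclei``; ``truth`` has one row per
    feature with the class means used and the label implied by ``lam``.
    """
    rng = np.random.default_rng(seed)
    classes = ("blast", "atypical", "promyelocyte")
    rows = []
    for i in range(recipe.n_patients):
        pid = f"P{i + 1:03d}"
        patient_effect = {
            name: rng.normal(0.0, math.sqrt(recipe.rho) * sd)
            for name, (_, _, sd) in recipe.features.items()
        }
        for cls in classes:
            row = {"patient_id": pid, "cell_class": cls,
                   "n_nuclei": recipe.n_nuclei_per_class}
            for name, (mb, mp, sd) in recipe.features.items():
                if cls == "blast":
                    mu = mb
                elif cls == "promyelocyte":
                    mu = mp
                else:
                    mu = recipe.lam * mb + (1.0 - recipe.lam) * mp
                resid = rng.normal(0.0, math.sqrt(1.0 - recipe.rho) * sd)
                row[name] = mu + patient_effect[name] + resid
            rows.append(row)
    table = pd.DataFrame(rows)
    truth = pd.DataFrame(
        {
            "feature": list(recipe.features),
            "mu_blast": [v[0] for v in recipe.features.values()],
            "mu_promyelocyte": [v[1] for v in recipe.features.values()],
            "sd": [v[2] for v in recipe.features.values()],
            "lam": recipe.lam,
            "expected_label": [
                expected_label(v[0], v[1], recipe.lam)
                for v in recipe.features.values()
            ],
        }
    )
    return table, truth


# --------------------------------------------------------------------------
# Image-level cohorts (end-to-end)
# --------------------------------------------------------------------------

def simulate_image_cohort(
    seed,
    n_patients: int = 4,
    n_nuclei_per_class: int = 8,
    lam: float = 0.5,
    mask_area_px: int = 2000,
    pixel_size: float = 0.1,
):
    """Yield NucleusImages for a small three-class cohort.

    Texture parameters of the atypical class are the lam-blend of the
    blast-like and promyelocyte-like presets.  ``mask_area_px`` defaults to
    a reduced size so a full pipeline run stays cheap; pass ~11500 for
    full-size (~115 um^2) nuclei.
    """
    def shrink(r: NucleusRecipe) -> NucleusRecipe:
        return replace(r, mask_area_px=int(mask_area_px * r.mask_area_px / 11800),
                       clump_sigma=r.clump_sigma * math.sqrt(mask_area_px / 11800),
                       clump_count=max(2, int(round(r.clump_count * mask_area_px / 11800))))

    recipes = {
        "blast": shrink(BLAST_LIKE),
        "atypical": shrink(blend_recipes(lam)),
        "promyelocyte": shrink(PROMYELOCYTE_LIKE),
    }
    root = np.random.SeedSequence(seed)
    for i, pseed in enumerate(root.spawn(n_patients)):
        pid = f"S{i + 1:03d}"
        class_seeds = pseed.spawn(3)
        for cls_seed, (cls, rec) in zip(class_seeds, recipes.items()):
            for j, nseed in enumerate(cls_seed.spawn(n_nuclei_per_class)):
                yield generate_nucleus(
                    rec, nseed, pixel_size=pixel_size,
                    patient_id=pid, cell_class=cls, cell_index=j,
                )
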