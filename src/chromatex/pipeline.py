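"""Per-nucleus feature extraction and batch processing.

One nucleus in, one row of the feature table out: morphometry, the seven
co-occurrence features, and the blanket fractal dimension with its
goodness of fit.  Batches are described either by an explicit manifest CSV
(columns: image_path, mask_path, patient_id, cell_class, cell_index) or by
the naming convention ``<stem>_mask.<ext>`` next to each image.
"""

from __future__ import annotations

import os
from typing import Iterable, Iterator, Optional

import pandas as pd

from .cooccurrence import build_glcm, glcm_features
from .fractal import fractal_dimension
from .imaging import NucleusImage, load_image, load_mask, make_nucleus
from .morphometry import morphometry as _morphometry

#: Column order of the per-nucleus feature table.
COLUMNS = (
    "patient_id",
    "cell_class",
    "cell_index",
    "area_px",
    "area_um2",
    "perimeter_px",
    "perimeter_um",
    "form_factor",
    "mean_gray",
    "sd_gray",
    "entropy",
    "inertia",
    "local_homogeneity",
    "energy_normalized",
    "energy_raw",
    "contrast",
    "diagonal_moment",
    "cluster_prominence",
    "fd_minkowski",
    "fd_r2",
)


def extract_features(
    nucleus: NucleusImage,
    glcm_distance: int = 1,
    glcm_levels: int = 256,
    eps_max: int = 10,
    ff_method: str = "circularity",
) -> dict:
    """All features of one nucleus as a flat dict (one CSV row)."""
    morph = _morphometry(nucleus, ff_method=ff_method)
    glcm = build_glcm(nucleus, distance=glcm_distance, levels=glcm_levels)
    tex = glcm_features(glcm)
    fit = fractal_dimension(nucleus, eps_max=eps_max)
    return {
        "patient_id": nucleus.patient_id,
        "cell_class": nucleus.cell_class,
        "cell_index": nucleus.cell_index,
        "area_px": morph.area_px,
        "area_um2": morph.area_um2,
        "perimeter_px": morph.perimeter_px,
        "perimeter_um": morph.perimeter_um,
        "form_factor": morph.form_factor,
        "mean_gray": morph.mean_gray,
        "sd_gray": morph.sd_gray,
        "entropy": tex.entropy,
        "inertia": tex.inertia,
        "local_homogeneity": tex.local_homogeneity,
        "energy_normalized": tex.energy_normalized,
        "energy_raw": tex.energy_raw,
        "contrast": tex.contrast,
        "diagonal_moment": tex.diagonal_moment,
        "cluster_prominence": tex.cluster_prominence,
        "fd_minkowski": fit.fd,
        "fd_r2": fit.r2,
    }


def process_nuclei(nuclei: Iterable[NucleusImage], **kwargs) -> pd.DataFrame:
    """Feature table for a batch of nuclei."""
    rows = [extract_features(n, **kwargs) for n in nuclei]
    return pd.DataFrame(rows, columns=COLUMNS)


def mask_path_for(image_path: str) -> str:
    """Mask location under the ``<stem>_mask.<ext>`` convention."""
    stem, ext = os.path.splitext(image_path)
    return f"{stem}_mask{ext}"


def load_nucleus(
    image_path: str,
    mask_path: Optional[str] = None,
    pixel_size: float = 0.1,
    patient_id: Optional[str] = None,
    cell_class: Optional[str] = None,
    cell_index: Optional[int] = None,
) -> NucleusImage:
    """Load an image and its mask (explicit path or naming convention)."""
    if mask_path is None:
        mask_path = mask_path_for(image_path)
    return make_nucleus(
        load_image(image_path),
        load_mask(mask_path),
        pixel_size=pixel_size,
        patient_id=patient_id,
        cell_class=cell_class,
        cell_index=cell_index,
    )


def iter_manifest(
    manifest_csv: str, pixel_size: float = 0.1
) -> Iterator[NucleusImage]:
    """Yield nuclei listed in a manifest CSV.

    Required columns: image_path, patient_id, cell_class, cell_index;
    optional: mask_path (falls back to the naming convention).  Relative
    paths are resolved against the manifest's directory.
    """
    manifest = pd.read_csv(manifest_csv)
    base = os.path.dirname(os.path.abspath(manifest_csv))

    def resolve(p):
        return p if os.path.isabs(p) else os.path.join(base, p)

    for _, row in manifest.iterrows():
        mask_path = row.get("mask_path")
        if isinstance(mask_path, str) and mask_path:
            mask_path = resolve(mask_path)
        else:
            mask_path = None
        yield load_nucleus(
            resolve(row["image_path"]),
            mask_path=mask_path,
            pixel_size=pixel_size,
            patient_id=str(row["patient_id"]),
            cell_class=row["cell_class"],
            cell_index=int(row["cell_index"]),
        )


def process_manifest(manifest_csv: str, out_csv: Optional[str] = None, **kwargs) -> pd.DataFrame:
    """Extract features for every nucleus in a manifest; optionally write CSV."""
    table = process_nuclei(iter_manifest(manifest_csv), **kwargs)
    if out_csv is not None:
        table.to_csv(out_csv, index=False)
    return table
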