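#!/usr/bin/env python
"""Simulate a small image-level cohort of granulocytic precursor nuclei.

Generates three-class nuclei (blast / atypical / promyelocyte) for a handful
of synthetic patients, with the atypical class's texture parameters halfway
between the blast-like and promyelocyte-like presets (lambda = 0.5), and
writes PNG images + masks and a manifest CSV under scratch/images/.

The images are scratch artefacts (regenerate them any time with this
script); the downstream feature tables written by 02 live under results/.
"""

import os
import sys

import pandas as pd

sys.path.insert(0, os.path.join(os.path.dirname(__file__), ".."))

from chromatex.imaging import save_image
from chromatex.synthetic import simulate_image_cohort

import imageio.v3 as iio
import numpy as np

OUT_DIR = os.path.join(os.path.dirname(__file__), "..", "scratch", "images")
N_PATIENTS = 6
N_NUCLEI = 10
LAMBDA = 0.5
MASK_AREA_PX = 2500  # reduced from ~11500 full-size for a fast demo run
SEED = 20260930


def main() -> None:
    os.makedirs(OUT_DIR, exist_ok=True)
    rows = []
    for i, nuc in enumerate(
        simulate_image_cohort(
            seed=SEED, n_patients=N_PATIENTS, n_nuclei_per_class=N_NUCLEI,
            lam=LAMBDA, mask_area_px=MASK_AREA_PX,
        )
    ):
        stem = f"{nuc.patient_id}_{nuc.cell_class}_{nuc.cell_index:02d}"
        save_image(nuc.image, os.path.join(OUT_DIR, f"{stem}.png"))
        iio.imwrite(
            os.path.join(OUT_DIR, f"{stem}_mask.png"),
            nuc.mask.pixels.astype(np.uint8) * 255,
        )
        rows.append(
            {
                "image_path": f"{stem}.png",
                "mask_path": f"{stem}_mask.png",
                "patient_id": nuc.patient_id,
                "cell_class": nuc.cell_class,
                "cell_index": nuc.cell_index,
            }
        )
    manifest = pd.DataFrame(rows)
    manifest_path = os.path.join(OUT_DIR, "manifest.csv")
    manifest.to_csv(manifest_path, index=False)
    print(f"wrote {len(manifest)} nuclei "
          f"({N_PATIENTS} patients x 3 classes x {N_NUCLEI}) to {OUT_DIR}")
    print(f"manifest: {manifest_path}")


if __name__ == "__main__":
    main()
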