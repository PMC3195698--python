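"""Published per-feature p-values for MDS granulocytic precursors.

The reference karyometry study of 30 MDS patients reported, for each of 14
nuclear features, three p-values — paired t blast vs atypical precursor,
paired t atypical vs promyelocyte, and the repeated-measures global test —
together with a verbal classification of the atypical class.  Those printed
p-values are the worked example for the significance-pattern rule: applying
``classify_atypical`` to them must reproduce the published labels (4
intermediate, 6 close-to-promyelocytes, 4 not defined, 0 close-to-blasts).

Entries printed as a bound (e.g. "<0.0001") are stored as the bound itself;
all such entries are far below alpha = 0.05, so labels are unaffected.
"""

from __future__ import annotations

import pandas as pd

from .stats_classify import LABELS, classify_atypical

#: (feature, p_blast_vs_atypical, p_atypical_vs_promyelocyte, p_global,
#:  published label)
REFERENCE_PVALUES = (
    ("area_um2", 0.95, 0.37, 0.60, "not_defined"),
    ("perimeter_px", 0.01, 0.004, 0.00001, "intermediate"),
    ("form_factor", 0.0001, 0.0005, 0.0001, "intermediate"),
    ("mean_gray", 0.0009, 0.0227, 0.00001, "intermediate"),
    ("sd_gray", 0.0001, 0.02, 0.01, "intermediate"),
    ("entropy", 0.11, 0.083, 0.01, "not_defined"),
    ("inertia", 0.0038, 0.095, 0.0001, "close_to_promyelocytes"),
    ("local_homogeneity", 0.32, 0.23, 0.12, "not_defined"),
    ("energy_raw", 0.00003, 0.39, 0.0001, "close_to_promyelocytes"),
    ("contrast", 0.0038, 0.095, 0.0001, "close_to_promyelocytes"),
    ("diagonal_moment", 0.00058, 0.098, 0.0001, "close_to_promyelocytes"),
    ("cluster_prominence", 0.021, 0.51, 0.018, "close_to_promyelocytes"),
    ("fd_minkowski", 0.0015, 0.82, 0.0015, "close_to_promyelocytes"),
    ("fd_r2", 0.026, 0.65, 0.068, "not_defined"),
)


def reference_table(alpha: float = 0.05) -> pd.DataFrame:
    """Classify the published p-value triples; one row per feature.

    Columns: the three p-values, the label computed by the rule, and the
    label printed in the reference study.
    """
    rows = []
    for feature, p_ba, p_ap, p_g, published in REFERENCE_PVALUES:
        rows.append(
            {
                "feature": feature,
                "p_blast_atyp": p_ba,
                "p_atyp_pro": p_ap,
                "p_global": p_g,
                "label": classify_atypical(p_ba, p_ap, p_g, alpha),
                "published_label": published,
            }
        )
    return pd.DataFrame(rows)


def reference_label_counts(alpha: float = 0.05) -> pd.Series:
    """Label counts over the 14 published feature rows."""
    return reference_table(alpha)["label"].value_counts().reindex(LABELS, fill_value=0)
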