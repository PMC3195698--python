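"""Patient-level statistics and the significance-pattern classification.

The statistical unit is the patient: each patient contributes one mean
value per feature per cell class (blast / atypical / promyelocyte),
averaged over at least ``min_nuclei`` (default 30) consecutive nuclei.
Three tests are used:

* paired t (within patients: blast vs atypical, atypical vs promyelocyte,
  and normal blast vs normal promyelocyte),
* pooled-variance Student t (between cohorts: normal vs MDS),
* one-way repeated-measures ANOVA across the three classes (global test;
  no sphericity correction, df = (2, 2(n-1))).

The four-outcome rule for each feature of the MDS cohort, at alpha = 0.05
(p = alpha counts as significant):

* global test not significant, or neither paired test significant
  -> ``not_defined``;
* both paired tests significant -> ``intermediate``;
* only blast-vs-atypical significant -> ``close_to_promyelocytes``;
* only atypical-vs-promyelocyte significant -> ``close_to_blasts``.

No multiple-testing adjustment is applied across features (each feature is
reported on its own); a Holm correction can be layered on by the caller.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .errors import (
    ConfigurationError,
    DegenerateTestError,
    InsufficientDataError,
)
from .synthetic import FEATURE_NAMES

LABELS = ("close_to_blasts", "close_to_promyelocytes", "intermediate", "not_defined")
_CLASSES = ("blast", "atypical", "promyelocyte")
_META_COLS = {"patient_id", "cell_class", "cell_index", "n_nuclei", "cohort"}


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: tuple  # (df,) for t tests, (df1, df2) for F
    p_value: float
    test_kind: str  # paired_t | independent_t | rm_anova


@dataclass(frozen=True)
class CohortTable:
    """Per-patient, per-class aggregated feature values."""

    data: pd.DataFrame  # columns: patient_id, cell_class, n_nuclei, features...
    label: Optional[str] = None  # "normal" | "MDS"

    @property
    def features(self) -> list:
        return [c for c in self.data.columns if c not in _META_COLS]

    def wide(self, feature: str) -> pd.DataFrame:
        """Patients x classes table for one feature (NaN where absent)."""
        return self.data.pivot(index="patient_id", columns="cell_class", values=feature)


def aggregate(
    per_nucleus: pd.DataFrame,
    min_nuclei: int = 30,
    strict: bool = False,
    label: Optional[str] = None,
) -> CohortTable:
    """Collapse a per-nucleus table to per-patient, per-class means.

    Groups with fewer than ``min_nuclei`` nuclei are excluded with a
    warning (or raise, with ``strict=True``).
    """
    required = {"patient_id", "cell_class"}
    missing = required - set(per_nucleus.columns)
    if missing:
        raise ConfigurationError(f"per-nucleus table lacks columns: {sorted(missing)}")
    feats = [
        c
        for c in per_nucleus.columns
        if c not in _META_COLS and pd.api.types.is_numeric_dtype(per_nucleus[c])
    ]
    rows = []
    for (pid, cls), grp in per_nucleus.groupby(["patient_id", "cell_class"], sort=True):
        n = len(grp)
        if n < min_nuclei:
            msg = (
                f"patient {pid} class {cls}: {n} nuclei < minimum {min_nuclei}; excluded"
            )
            if strict:
                raise InsufficientDataError(msg)
            warnings.warn(msg, stacklevel=2)
            continue
        row = {"patient_id": pid, "cell_class": cls, "n_nuclei": n}
        row.update(grp[feats].mean().to_dict())
        rows.append(row)
    return CohortTable(data=pd.DataFrame(rows), label=label)


# --------------------------------------------------------------------------
# Tests
# --------------------------------------------------------------------------

def paired_t(x: Sequence[float], y: Sequence[float]) -> TestResult:
    """Two-sided paired t test; pairs with a missing side are dropped."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ConfigurationError("paired samples must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    n = x.size
    if n < 3:
        raise InsufficientDataError(f"paired t needs >= 3 complete pairs, got {n}")
    d = x - y
    if d.std(ddof=1) == 0:
        raise DegenerateTestError("zero variance of paired differences")
    res = sps.ttest_rel(x, y)
    return TestResult(
        statistic=float(res.statistic),
        df=(n - 1,),
        p_value=float(res.pvalue),
        test_kind="paired_t",
    )


def independent_t(x: Sequence[float], y: Sequence[float], welch: bool = False) -> TestResult:
    """Two-sided two-sample t; pooled variance unless ``welch``."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    x, y = x[~np.isnan(x)], y[~np.isnan(y)]
    if x.size < 2 or y.size < 2:
        raise InsufficientDataError("independent t needs >= 2 values per group")
    if not welch and x.std(ddof=1) == 0 and y.std(ddof=1) == 0:
        raise DegenerateTestError("zero pooled variance")
    res = sps.ttest_ind(x, y, equal_var=not welch)
    df = (res.df,) if welch else (x.size + y.size - 2,)
    return TestResult(
        statistic=float(res.statistic),
        df=tuple(float(v) for v in df),
        p_value=float(res.pvalue),
        test_kind="independent_t",
    )


def rm_anova(values) -> TestResult:
    """One-way repeated-measures ANOVA over the three cell classes.

    ``values``: (n_patients, k) array or DataFrame, one column per class.
    Rows with any missing value are dropped with a warning.  The subject
    effect is removed; F = MS_class / MS_error with df (k-1, (k-1)(n-1)).
    """
    arr = np.asarray(values, dtype=float)
    if arr.ndim != 2 or arr.shape[1] < 2:
        raise ConfigurationError("rm_anova needs a patients x classes table")
    complete = ~np.isnan(arr).any(axis=1)
    if not complete.all():
        warnings.warn(
            f"dropping {int((~complete).sum())} incomplete patient row(s)",
            stacklevel=2,
        )
    arr = arr[complete]
    n, k = arr.shape
    if n < 3:
        raise InsufficientDataError(f"rm_anova needs >= 3 complete patients, got {n}")
    grand = arr.mean()
    ss_subject = k * float(((arr.mean(axis=1) - grand) ** 2).sum())
    ss_class = n * float(((arr.mean(axis=0) - grand) ** 2).sum())
    ss_total = float(((arr - grand) ** 2).sum())
    ss_error = ss_total - ss_subject - ss_class
    df_class = k - 1
    df_error = (k - 1) * (n - 1)
    ms_error = ss_error / df_error
    tiny = 1e-12 * max(1.0, grand**2)
    if ms_error <= tiny:
        # no class effect either: F = 0/0 resolves to "no evidence"
        if ss_class <= tiny:
            return TestResult(
                statistic=0.0, df=(df_class, df_error), p_value=1.0,
                test_kind="rm_anova",
            )
        raise DegenerateTestError("zero within-patient error variance")
    f = (ss_class / df_class) / ms_error
    p = float(sps.f.sf(f, df_class, df_error))
    return TestResult(
        statistic=float(f), df=(df_class, df_error), p_value=p, test_kind="rm_anova"
    )


# --------------------------------------------------------------------------
# Classification
# --------------------------------------------------------------------------

def classify_atypical(
    p_blast_atyp: float, p_atyp_pro: float, p_global: float, alpha: float = 0.05
) -> str:
    """Four-outcome label from the three p-values (p = alpha is significant)."""
    for name, p in (
        ("p_blast_atyp", p_blast_atyp),
        ("p_atyp_pro", p_atyp_pro),
        ("p_global", p_global),
    ):
        if not 0.0 <= p <= 1.0:
            raise ValueError(f"{name}={p} outside [0, 1]")
    if p_global > alpha:
        return "not_defined"
    sig_ba = p_blast_atyp <= alpha
    sig_ap = p_atyp_pro <= alpha
    if not sig_ba and not sig_ap:
        return "not_defined"
    if sig_ba and sig_ap:
        return "intermediate"
    if sig_ba:
        return "close_to_promyelocytes"
    return "close_to_blasts"


@dataclass(frozen=True)
class ClassComparison:
    feature: str
    p_blast_atyp: float
    p_atyp_pro: float
    p_global: float
    label: str
    alpha: float = 0.05


# --------------------------------------------------------------------------
# Reports
# --------------------------------------------------------------------------

def compare_cohorts(normal: CohortTable, mds: CohortTable) -> pd.DataFrame:
    """Normal-marrow and cross-cohort comparisons, one row per feature.

    Columns: paired blast-vs-promyelocyte within the normal cohort, and
    pooled t of normal vs MDS for blasts and for promyelocytes, with the
    class means alongside.  Features whose classes are missing are skipped
    with a warning.
    """
    feats = [f for f in normal.features if f in set(mds.features)]
    rows = []
    for feat in feats:
        nw = normal.wide(feat)
        mw = mds.wide(feat)
        row = {"feature": feat}
        try:
            nb = nw["blast"].dropna()
            npro = nw["promyelocyte"].dropna()
            row["mean_normal_blast"] = float(nb.mean())
            row["mean_normal_promyelocyte"] = float(npro.mean())
            paired = nw[["blast", "promyelocyte"]].dropna()
            res = paired_t(paired["blast"], paired["promyelocyte"])
            row["p_normal_blast_vs_pro"] = res.p_value
        except (KeyError, InsufficientDataError, DegenerateTestError) as exc:
            warnings.warn(f"{feat}: normal paired comparison skipped ({exc})", stacklevel=2)
        for cls, tag in (("blast", "blasts"), ("promyelocyte", "promyelocytes")):
            try:
                xs = nw[cls].dropna()
                ys = mw[cls].dropna()
                row[f"mean_mds_{cls}"] = float(ys.mean())
                res = independent_t(xs, ys)
                row[f"p_normal_vs_mds_{tag}"] = res.p_value
            except (KeyError, InsufficientDataError, DegenerateTestError) as exc:
                warnings.warn(f"{feat}: {tag} cohort comparison skipped ({exc})", stacklevel=2)
        if len(row) > 1:
            rows.append(row)
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class Table5Report:
    """Per-feature three-class means, the three p-values, and the label."""

    table: pd.DataFrame  # feature, means, p_blast_atyp, p_atyp_pro, p_global, label
    alpha: float

    @property
    def label_counts(self) -> pd.Series:
        return self.table["label"].value_counts().reindex(LABELS, fill_value=0)


def classify_all(mds: CohortTable, alpha: float = 0.05) -> Table5Report:
    """Full per-feature analysis of an MDS cohort table.

    For each feature: the three class means, two paired t tests
    (blast vs atypical, atypical vs promyelocyte), the repeated-measures
    global test, and the significance-pattern label.
    """
    rows = []
    for feat in mds.features:
        wide = mds.wide(feat)
        for cls in _CLASSES:
            if cls not in wide.columns:
                raise InsufficientDataError(f"feature {feat}: class {cls} missing")
        wide = wide[list(_CLASSES)].dropna()
        if len(wide) < 3:
            raise InsufficientDataError(
                f"feature {feat}: fewer than 3 complete patients"
            )
        p_ba = paired_t(wide["blast"], wide["atypical"]).p_value
        p_ap = paired_t(wide["atypical"], wide["promyelocyte"]).p_value
        p_g = rm_anova(wide.values).p_value
        rows.append(
            {
                "feature": feat,
                "mean_blast": float(wide["blast"].mean()),
                "mean_atypical": float(wide["atypical"].mean()),
                "mean_promyelocyte": float(wide["promyelocyte"].mean()),
                "p_blast_atyp": p_ba,
                "p_atyp_pro": p_ap,
                "p_global": p_g,
                "label": classify_atypical(p_ba, p_ap, p_g, alpha),
            }
        )
    return Table5Report(table=pd.DataFrame(rows), alpha=alpha)
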