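"""Patient-level tests, the four-outcome rule, and the cohort reports."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from chromatex.errors import (
    ConfigurationError,
    DegenerateTestError,
    InsufficientDataError,
)
from chromatex.reference import REFERENCE_PVALUES, reference_label_counts
from chromatex.stats_classify import (
    LABELS,
    CohortTable,
    aggregate,
    classify_all,
    classify_atypical,
    compare_cohorts,
    independent_t,
    paired_t,
    rm_anova,
)
from chromatex.synthetic import CohortRecipe, simulate_cohort


class TestPairedT:
    def test_closed_form(self):
        # differences {1, 2, 3}: t = 2 / (1/sqrt(3)) = 2*sqrt(3)
        res = paired_t([2, 4, 6], [1, 2, 3])
        assert res.statistic == pytest.approx(3.4641, abs=1e-4)
        assert res.df == (2,)
        assert res.p_value == pytest.approx(0.0742, abs=1e-4)

    def test_identical_samples_degenerate(self):
        with pytest.raises(DegenerateTestError):
            paired_t([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])

    def test_antisymmetry(self, rng):
        x = rng.normal(size=8)
        y = rng.normal(size=8)
        a, b = paired_t(x, y), paired_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_value == pytest.approx(b.p_value)

    def test_missing_pairs_dropped(self):
        res = paired_t([2, 4, 6, np.nan], [1, 2, 3, 9])
        assert res.df == (2,)

    def test_too_few_pairs(self):
        with pytest.raises(InsufficientDataError):
            paired_t([1, 2], [0, 0])


class TestIndependentT:
    def test_identical_groups(self):
        res = independent_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_zero_variance_degenerate(self):
        with pytest.raises(DegenerateTestError):
            independent_t([0, 0, 0, 0], [1, 1, 1, 1])

    def test_pooled_closed_form(self):
        res = independent_t([1, 2, 3, 4], [3, 4, 5, 6])
        assert res.statistic == pytest.approx(-2.1909, abs=1e-4)
        assert res.df == (6,)
        assert res.p_value == pytest.approx(0.0710, abs=1e-4)

    def test_welch_variant(self):
        res = independent_t([1, 2, 3, 4], [3, 4, 5, 60], welch=True)
        assert res.test_kind == "independent_t"
        assert 0 <= res.p_value <= 1


def _ss_oracle(arr):
    """Literal sum-of-squares decomposition for within-subject ANOVA."""
    n, k = arr.shape
    gm = arr.mean()
    ss_sub = sum(k * (arr[i].mean() - gm) ** 2 for i in range(n))
    ss_cls = sum(n * (arr[:, j].mean() - gm) ** 2 for j in range(k))
    ss_tot = sum((arr[i, j] - gm) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_tot - ss_sub - ss_cls
    f = (ss_cls / (k - 1)) / (ss_err / ((k - 1) * (n - 1)))
    return f


class TestRmAnova:
    def test_no_class_effect(self):
        # classes identical within each patient, patients differ
        vals = np.array([[1.0, 1, 1], [5, 5, 5], [9, 9, 9], [2, 2, 2]])
        res = rm_anova(vals)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_pure_class_effect_is_degenerate(self):
        # additive class effect {0,1,2}, zero noise: MS_error = 0
        vals = np.arange(3)[None, :] + np.arange(4)[:, None] * 10.0
        with pytest.raises(DegenerateTestError):
            rm_anova(vals)

    def test_matches_ss_oracle(self, rng):
        vals = rng.normal(size=(7, 3))
        res = rm_anova(vals)
        assert res.statistic == pytest.approx(_ss_oracle(vals), abs=1e-10)
        assert res.df == (2, 12)

    def test_matches_pingouin(self, rng):
        pg = pytest.importorskip("pingouin")
        vals = rng.normal(size=(9, 3)) + np.array([0.0, 0.4, 0.9])
        long = pd.DataFrame(
            {
                "y": vals.ravel(),
                "subj": np.repeat(np.arange(9), 3),
                "cls": np.tile(np.arange(3), 9),
            }
        )
        table = pg.rm_anova(data=long, dv="y", within="cls", subject="subj")
        res = rm_anova(vals)
        assert res.statistic == pytest.approx(float(table["F"][0]), rel=1e-6)
        assert res.p_value == pytest.approx(float(table["p_unc"][0]), rel=1e-6)

    def test_two_class_equals_paired_t_squared(self, rng):
        for _ in range(5):
            vals = rng.normal(size=(8, 2)) + np.array([0.0, 0.5])
            f = rm_anova(vals).statistic
            t = paired_t(vals[:, 0], vals[:, 1]).statistic
            assert f == pytest.approx(t**2, abs=1e-9)

    def test_incomplete_rows_dropped(self, rng):
        vals = rng.normal(size=(5, 3))
        vals[0, 1] = np.nan
        with pytest.warns(UserWarning, match="incomplete"):
            res = rm_anova(vals)
        assert res.df == (2, 6)  # 4 complete patients

    def test_insufficient_patients(self):
        with pytest.raises(InsufficientDataError):
            rm_anova(np.array([[1.0, 2, 3], [2, 1, 4]]))


class TestClassifyAtypical:
    @pytest.mark.parametrize("feature, p_ba, p_ap, p_g, expected", REFERENCE_PVALUES)
    def test_published_rows(self, feature, p_ba, p_ap, p_g, expected):
        assert classify_atypical(p_ba, p_ap, p_g) == expected

    def test_close_to_blasts_pattern(self):
        # only atypical-vs-promyelocyte significant
        assert classify_atypical(0.07, 0.01, 0.001) == "close_to_blasts"

    def test_boundary_p_equal_alpha_is_significant(self):
        assert classify_atypical(0.05, 0.05, 0.05) == "intermediate"

    @pytest.mark.parametrize(
        "sig_ba, sig_ap, sig_g",
        [(a, b, g) for a in (0, 1) for b in (0, 1) for g in (0, 1)],
    )
    def test_exhaustive_significance_patterns(self, sig_ba, sig_ap, sig_g):
        p = lambda sig: 0.01 if sig else 0.5
        label = classify_atypical(p(sig_ba), p(sig_ap), p(sig_g))
        if not sig_g or (not sig_ba and not sig_ap):
            assert label == "not_defined"
        elif sig_ba and sig_ap:
            assert label == "intermediate"
        elif sig_ba:
            assert label == "close_to_promyelocytes"
        else:
            assert label == "close_to_blasts"

    @given(
        p_ba=st.floats(0, 1), p_ap=st.floats(0, 1), p_g=st.floats(0, 1),
        alpha=st.floats(0.001, 0.2),
    )
    @settings(deadline=None, max_examples=500)
    def test_total_and_deterministic(self, p_ba, p_ap, p_g, alpha):
        label = classify_atypical(p_ba, p_ap, p_g, alpha)
        assert label in LABELS
        assert classify_atypical(p_ba, p_ap, p_g, alpha) == label

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            classify_atypical(1.2, 0.5, 0.5)

    def test_published_label_counts(self):
        counts = reference_label_counts()
        assert counts["intermediate"] == 4
        assert counts["close_to_promyelocytes"] == 6
        assert counts["not_defined"] == 4
        assert counts["close_to_blasts"] == 0


def _per_nucleus_frame(n_patients=2, n_nuclei=30, classes=("blast", "promyelocyte")):
    rows = []
    for i in range(n_patients):
        for cls in classes:
            for j in range(n_nuclei):
                rows.append(
                    {
                        "patient_id": f"P{i}",
                        "cell_class": cls,
                        "cell_index": j,
                        "feat": float(i),
                    }
                )
    return pd.DataFrame(rows)


class TestAggregate:
    def test_basic_shape(self):
        table = aggregate(_per_nucleus_frame())
        assert len(table.data) == 4
        assert table.features == ["feat"]

    def test_constant_nuclei_give_patient_mean(self):
        table = aggregate(_per_nucleus_frame())
        assert set(table.data.loc[table.data.patient_id == "P1", "feat"]) == {1.0}

    def test_below_minimum_excluded_with_warning(self):
        df = _per_nucleus_frame()
        df = df.drop(df[(df.patient_id == "P0") & (df.cell_class == "blast")].index[:1])
        with pytest.warns(UserWarning, match="29 nuclei"):
            table = aggregate(df)
        assert len(table.data) == 3

    def test_strict_mode_raises(self):
        df = _per_nucleus_frame(n_nuclei=10)
        with pytest.raises(InsufficientDataError):
            aggregate(df, strict=True)

    def test_missing_columns(self):
        with pytest.raises(ConfigurationError):
            aggregate(pd.DataFrame({"x": [1.0]}))


def _cohort_from_sim(lam, seed, features=None, **kw):
    recipe = CohortRecipe(lam=lam, **({"features": features} if features else {}), **kw)
    table, truth = simulate_cohort(recipe, seed)
    return CohortTable(data=table, label="MDS"), truth


class TestCompareCohorts:
    def test_identical_cohorts_all_p_one(self):
        cohort, _ = _cohort_from_sim(0.5, 7)
        report = compare_cohorts(cohort, cohort)
        assert np.allclose(report["p_normal_vs_mds_blasts"], 1.0)
        assert np.allclose(report["p_normal_vs_mds_promyelocytes"], 1.0)

    def test_empty_mds_table_gives_empty_report(self):
        cohort, _ = _cohort_from_sim(0.5, 7)
        empty = CohortTable(data=pd.DataFrame(), label="MDS")
        report = compare_cohorts(cohort, empty)
        assert report.empty

    def test_one_sd_shift_detected_at_theoretical_power(self):
        """Power oracle: a +1 SD shift of one feature, 19 vs 30 patients, is
        detected (p <= 0.05) at the closed-form noncentral-t power (~0.92)."""
        from scipy import stats as sps

        n_rep = 400
        hits = 0
        root = np.random.SeedSequence(424242)
        for ss in root.spawn(n_rep):
            rng = np.random.default_rng(ss)
            x = rng.normal(0.0, 1.0, size=19)
            y = rng.normal(1.0, 1.0, size=30)
            if independent_t(x, y).p_value <= 0.05:
                hits += 1
        ncp = 1.0 / np.sqrt(1 / 19 + 1 / 30)
        t_crit = sps.t.ppf(0.975, 47)
        power = sps.nct.sf(t_crit, 47, ncp) + sps.nct.cdf(-t_crit, 47, ncp)
        assert power > 0.90  # the design itself is adequately powered
        rate = hits / n_rep
        tol = 3.5 * np.sqrt(power * (1 - power) / n_rep)
        assert abs(rate - power) < tol


class TestClassifyAll:
    def test_report_shape_and_labels(self):
        cohort, truth = _cohort_from_sim(0.0, 11)
        report = classify_all(cohort)
        assert set(report.table["feature"]) == set(truth["feature"])
        assert report.table["label"].isin(LABELS).all()
        assert report.label_counts.sum() == len(report.table)

    def test_missing_class_raises(self):
        cohort, _ = _cohort_from_sim(0.5, 3)
        data = cohort.data[cohort.data.cell_class != "atypical"]
        with pytest.raises(InsufficientDataError):
            classify_all(CohortTable(data=data))
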