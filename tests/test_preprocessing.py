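import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import normvol as nv
from normvol.preprocessing import IntegrityError

from conftest import make_records


def one_subject(sid="s1", group="ND", method="segA", **kw):
    base = dict(age=60.0, sex=1, height=170.0)
    base.update(kw)
    return sid, base["age"], base["sex"], base["height"], group, method


class TestMergeHemispheres:
    def test_left_plus_right_sums(self):
        df = make_records([
            (*one_subject(), "thalamus", "left", 1000.0),
            (*one_subject(), "thalamus", "right", 1100.0),
        ])
        out = nv.merge_hemispheres(nv.CohortTable(df)).df
        assert len(out) == 1
        assert out.iloc[0]["hemisphere"] == "both"
        assert out.iloc[0]["volume_mm3"] == 2100.0

    def test_already_merged_passes_through(self):
        df = make_records([(*one_subject(), "thalamus", "both", 2100.0)])
        out = nv.merge_hemispheres(nv.CohortTable(df)).df
        assert out.iloc[0]["volume_mm3"] == 2100.0

    def test_single_hemisphere_becomes_failed(self):
        df = make_records([(*one_subject(), "thalamus", "left", 1000.0)])
        out = nv.merge_hemispheres(nv.CohortTable(df)).df
        assert len(out) == 1
        assert np.isnan(out.iloc[0]["volume_mm3"])

    def test_failed_hemisphere_fails_the_merge(self):
        df = make_records([
            (*one_subject(), "thalamus", "left", np.nan),
            (*one_subject(), "thalamus", "right", 1100.0),
        ])
        out = nv.merge_hemispheres(nv.CohortTable(df)).df
        assert np.isnan(out.iloc[0]["volume_mm3"])

    def test_mixed_both_and_sided_rows_rejected(self):
        df = make_records([
            (*one_subject(), "thalamus", "both", 2100.0),
            (*one_subject(), "thalamus", "left", 1000.0),
        ])
        with pytest.raises(IntegrityError):
            nv.merge_hemispheres(nv.CohortTable(df))


class TestMergeCaudateAccumbens:
    def test_sources_sum_into_combined_region(self):
        df = make_records([
            (*one_subject(), "caudate_nucleus", "both", 7000.0),
            (*one_subject(), "accumbens", "both", 500.0),
        ])
        out = nv.merge_caudate_accumbens(nv.CohortTable(df)).df
        assert list(out["region"]) == ["caudate_nucleus_accumbens"]
        assert out.iloc[0]["volume_mm3"] == 7500.0

    def test_premerged_method_relabeled_unchanged(self):
        df = make_records([
            (*one_subject(method="segE"), "caudate_nucleus_accumbens", "both", 7280.0),
        ])
        out = nv.merge_caudate_accumbens(nv.CohortTable(df), {"segE"}).df
        assert out.iloc[0]["volume_mm3"] == 7280.0
        assert out.iloc[0]["region"] == "caudate_nucleus_accumbens"

    def test_missing_source_marks_combined_failed(self):
        df = make_records([
            (*one_subject(), "caudate_nucleus", "both", 7000.0),
            (*one_subject(), "accumbens", "both", np.nan),
            (*one_subject(sid="s2"), "caudate_nucleus", "both", 6800.0),
        ])
        out = nv.merge_caudate_accumbens(nv.CohortTable(df)).df
        assert out["volume_mm3"].isna().all()

    def test_other_regions_untouched(self):
        df = make_records([
            (*one_subject(), "thalamus", "both", 12000.0),
            (*one_subject(), "caudate_nucleus", "both", 7000.0),
            (*one_subject(), "accumbens", "both", 500.0),
        ])
        out = nv.merge_caudate_accumbens(nv.CohortTable(df)).df
        assert set(out["region"]) == {"thalamus", "caudate_nucleus_accumbens"}


class TestExcludeFailures:
    def test_no_failures_is_identity_with_zero_counts(self, tiny_table):
        out, report = nv.exclude_failures(tiny_table)
        assert out.df[["subject_id", "volume_mm3"]].equals(
            tiny_table.df[["subject_id", "volume_mm3"]])
        assert (report.failures["n_failed"] == 0).all()

    def test_single_failure_removes_exactly_that_record(self, tiny_table):
        df = tiny_table.df.copy()
        df.loc[1, "volume_mm3"] = np.nan
        out, report = nv.exclude_failures(nv.CohortTable(df))
        assert len(out.df) == 2
        assert "s2" not in set(out.df["subject_id"])
        assert report.failures.set_index(["method", "region"]).loc[
            ("segA", "thalamus"), "n_failed"] == 1

    def test_failure_scoped_to_method(self):
        rows = []
        for m in ("segA", "segB"):
            for r in ("thalamus", "putamen"):
                rows.append((*one_subject(method=m), r, "both",
                             np.nan if m == "segA" else 8000.0))
        out, _ = nv.exclude_failures(nv.CohortTable(make_records(rows)))
        assert set(out.df["method"]) == {"segB"}
        assert len(out.df) == 2


class TestDetectOutliers:
    def test_constant_values_have_no_outliers(self):
        assert not nv.detect_outliers([5.0] * 10).any()

    def test_default_threshold_is_five(self):
        import inspect
        sig = inspect.signature(nv.detect_outliers)
        assert sig.parameters["threshold"].default == 5.0

    def test_single_gross_value_flagged(self):
        """999 zeros and one 100: mean 0.1, SD ~3.161, so only the 100 is
        beyond 5 population SDs (its z ~31.6)."""
        values = np.zeros(1000)
        values[-1] = 100.0
        mask = nv.detect_outliers(values, 5.0)
        assert mask.sum() == 1 and mask[-1]

    def test_fewer_than_two_values_rejected(self):
        with pytest.raises(ValueError):
            nv.detect_outliers([1.0])

    @given(st.floats(-1e3, 1e3), st.floats(0.01, 1e3))
    def test_affine_invariance(self, shift, scale):
        rng = np.random.default_rng(5)
        v = rng.normal(0, 1, 200)
        v[0] = 50.0
        base = nv.detect_outliers(v, 5.0)
        transformed = nv.detect_outliers(scale * v + shift, 5.0)
        assert (base == transformed).all()


class TestApplyRegionExclusion:
    def _cohort_with_outlier(self):
        rows = []
        rng = np.random.default_rng(0)
        for i in range(40):
            for m in ("segA", "segB"):
                for r in ("thalamus", "amygdala"):
                    v = 12000 + 100 * rng.standard_normal()
                    rows.append((f"s{i}", 60.0 + i, i % 2, 170.0, "ND", m, r, "both", v))
        df = make_records(rows)
        # subject s0 grossly outlying for amygdala under both methods
        df.loc[(df["subject_id"] == "s0") & (df["region"] == "amygdala"),
               "volume_mm3"] = 1e6
        return nv.CohortTable(df)

    def test_no_outliers_keeps_everyone(self, tiny_table):
        out, report = nv.apply_region_exclusion(tiny_table, 5.0)
        assert len(out.df) == len(tiny_table.df)
        assert report.included_n["thalamus"] == 3

    def test_union_rule_counts_subject_once(self):
        out, report = nv.apply_region_exclusion(self._cohort_with_outlier(), 5.0)
        assert report.excluded_subjects["amygdala"] == ["s0"]
        assert report.included_n["amygdala"] == 39
        # flagged by two methods but removed once, for all methods
        assert not ((out.df["subject_id"] == "s0")
                    & (out.df["region"] == "amygdala")).any()

    def test_exclusion_is_region_scoped(self):
        out, report = nv.apply_region_exclusion(self._cohort_with_outlier(), 5.0)
        assert report.included_n["thalamus"] == 40
        assert ((out.df["subject_id"] == "s0")
                & (out.df["region"] == "thalamus")).sum() == 2

    def test_included_plus_excluded_reconciles(self):
        table = self._cohort_with_outlier()
        _, report = nv.apply_region_exclusion(table, 5.0)
        for region in ("thalamus", "amygdala"):
            total = table.df[(table.df["region"] == region)
                             & (table.df["group"] == "ND")]["subject_id"].nunique()
            assert report.included_n[region] + len(report.excluded_subjects[region]) == total

    def test_ad_records_only_removed_via_explicit_flag(self):
        df = self._cohort_with_outlier().df.copy()
        ad = make_records([
            ("p1", 80.0, 1, 170.0, "AD", "segA", "amygdala", "both", 1e6),
            ("p2", 82.0, 0, 165.0, "AD", "segA", "amygdala", "both", 2000.0),
        ])
        ad["exclude"] = [1, 0]
        df["exclude"] = 0
        import pandas as pd
        table = nv.CohortTable(pd.concat([df, ad], ignore_index=True))
        out, _ = nv.apply_region_exclusion(table, 5.0)
        kept_ad = out.df[out.df["group"] == "AD"]["subject_id"]
        assert set(kept_ad) == {"p2"}
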