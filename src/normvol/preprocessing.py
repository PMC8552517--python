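"""Region harmonization and exclusion of failed / outlying segmentations.

Order of operations in the pipeline: hemispheres are summed into a single
bilateral volume, the caudate nucleus and accumbens are merged into one
region (methods that already segment them jointly pass through), failed
segmentations are removed, and finally reference-group volumes with an
extreme population z-score are excluded region-wise.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd

from .data_io import CohortTable
from .synthetic import REGION_ACCUMBENS, REGION_CAUDATE, REGION_CAUDATE_ACCUMBENS

log = logging.getLogger("normvol")

DEFAULT_OUTLIER_THRESHOLD = 5.0


class IntegrityError(ValueError):
    """Raised when a table violates structural assumptions (e.g. duplicate
    hemisphere rows)."""


@dataclasses.dataclass
class ExclusionReport:
    """Book-keeping of removed records.

    failures : DataFrame indexed by (method, region) with failure counts.
    outliers : DataFrame indexed by (method, region) with outlier counts.
    excluded_subjects : dict region -> sorted list of excluded subject ids.
    included_n : dict region -> number of subjects remaining.
    """

    failures: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=["method", "region", "n_failed"]))
    outliers: pd.DataFrame = dataclasses.field(
        default_factory=lambda: pd.DataFrame(columns=["method", "region", "n_outliers"]))
    excluded_subjects: dict = dataclasses.field(default_factory=dict)
    included_n: dict = dataclasses.field(default_factory=dict)

    def to_table(self, methods: list[str] | None = None) -> pd.DataFrame:
        """Wide per-region table: one outlier-count column per method plus
        the number of subjects included (mirrors a study exclusion table)."""
        if self.outliers.empty:
            return pd.DataFrame()
        wide = self.outliers.pivot_table(index="region", columns="method",
                                         values="n_outliers", fill_value=0, aggfunc="sum")
        if methods:
            wide = wide.reindex(columns=methods, fill_value=0)
        wide["total_n"] = [self.included_n.get(r, np.nan) for r in wide.index]
        return wide.reset_index()


def merge_hemispheres(table: CohortTable) -> CohortTable:
    """Sum left and right hemisphere volumes into a single bilateral record.

    Records already marked ``both`` pass through unchanged.  A subject with
    only one hemisphere present (or one hemisphere failed) yields a failed
    bilateral record — an incomplete segmentation is no segmentation.
    """
    df = table.df
    key = ["subject_id", "method", "region", "hemisphere"]
    if df.duplicated(subset=key).any():
        raise IntegrityError("duplicate hemisphere rows for the same (subject, method, region)")

    both = df[df["hemisphere"] == "both"]
    lr = df[df["hemisphere"] != "both"]
    if len(lr):
        grp_cols = ["subject_id", "method", "region"]
        # conflicting 'both' + sided rows for the same cell are ambiguous
        overlap = pd.merge(both[grp_cols], lr[grp_cols].drop_duplicates(), on=grp_cols)
        if len(overlap):
            raise IntegrityError("records mixing 'both' with sided hemispheres for the same cell")
        agg = {c: (c, "first") for c in ("age", "sex", "height", "group")}
        if "exclude" in df.columns:
            agg["exclude"] = ("exclude", "max")
        merged = lr.groupby(grp_cols, as_index=False).agg(
            n_hemi=("hemisphere", "nunique"),
            volume_mm3=("volume_mm3", lambda v: v.sum(min_count=2)),
            **agg,
        )
        # a single-hemisphere record is incomplete -> failed
        merged.loc[merged["n_hemi"] < 2, "volume_mm3"] = np.nan
        merged["hemisphere"] = "both"
        merged = merged.drop(columns="n_hemi")
        out = pd.concat([both, merged], ignore_index=True)
    else:
        out = both
    cols = [c for c in df.columns]
    out = out.loc[:, cols].sort_values(["group", "subject_id", "method", "region"],
                                       ascending=[True, True, True, True])
    return table.replace_df(out, hemispheres_merged=True)


def merge_caudate_accumbens(table: CohortTable,
                            premerged_methods: set[str] | frozenset[str] = frozenset(),
                            caudate: str = REGION_CAUDATE,
                            accumbens: str = REGION_ACCUMBENS,
                            merged: str = REGION_CAUDATE_ACCUMBENS) -> CohortTable:
    """Combine the caudate nucleus and accumbens into one region.

    Methods in ``premerged_methods`` already report the combined structure;
    their record is relabeled to ``merged``.  For every other method the two
    source volumes are summed; if either source is missing or failed, the
    combined record is failed.
    """
    df = table.df.copy()
    is_pre = df["method"].isin(premerged_methods)
    # relabel the premerged methods' combined region (tolerate either name)
    df.loc[is_pre & df["region"].isin([merged, caudate]), "region"] = merged

    src = df[~is_pre & df["region"].isin([caudate, accumbens])]
    rest = df[~df.index.isin(src.index)]
    if len(src):
        grp_cols = ["subject_id", "method", "hemisphere"]
        agg = {c: (c, "first") for c in ("age", "sex", "height", "group")}
        if "exclude" in df.columns:
            agg["exclude"] = ("exclude", "max")
        combined = src.groupby(grp_cols, as_index=False).agg(
            n_src=("region", "nunique"),
            volume_mm3=("volume_mm3", lambda v: v.sum(min_count=2)),
            **agg,
        )
        combined.loc[combined["n_src"] < 2, "volume_mm3"] = np.nan
        combined["region"] = merged
        combined = combined.drop(columns="n_src")
        out = pd.concat([rest, combined.loc[:, [c for c in df.columns]]], ignore_index=True)
    else:
        out = rest
    out = out.sort_values(["group", "subject_id", "method", "region"])
    return table.replace_df(out, caudate_accumbens_merged=True)


def exclude_failures(table: CohortTable) -> tuple[CohortTable, ExclusionReport]:
    """Drop failed (missing-volume) records and tally them per method/region."""
    df = table.df
    failed = df["volume_mm3"].isna()
    report = ExclusionReport()
    counts = (df[failed].groupby(["method", "region"]).size()
              .rename("n_failed").reset_index())
    all_cells = df[["method", "region"]].drop_duplicates()
    report.failures = all_cells.merge(counts, on=["method", "region"], how="left").fillna(
        {"n_failed": 0}).astype({"n_failed": int})
    out = df[~failed]
    log.info("excluded %d failed records", int(failed.sum()))
    return table.replace_df(out, failures_excluded=int(failed.sum())), report


def detect_outliers(values, threshold: float = DEFAULT_OUTLIER_THRESHOLD) -> np.ndarray:
    """Flag values whose population z-score exceeds the threshold.

    The mean and SD (n-1 denominator) are computed over *all* supplied
    values in a single pass — candidate outliers included, no trimming, no
    iteration.  A zero-SD (constant) sample has no outliers.
    """
    values = np.asarray(values, dtype=float)
    if values.size < 2:
        raise ValueError("need at least 2 values for outlier detection")
    sd = np.std(values, ddof=1)
    if sd == 0.0:
        return np.zeros(values.shape, dtype=bool)
    z = (values - np.mean(values)) / sd
    return np.abs(z) > threshold


def apply_region_exclusion(table: CohortTable,
                           threshold: float = DEFAULT_OUTLIER_THRESHOLD
                           ) -> tuple[CohortTable, ExclusionReport]:
    """Region-wise removal of outlying reference subjects.

    For every region, outlier detection runs per method over the ND
    volumes; a subject flagged by *any* method is excluded from that
    region's analysis for *all* methods (union rule — regions end up with
    differing included counts).  AD records are never auto-excluded by
    z-score; they are dropped only when their input ``exclude`` flag is set
    (standing in for visual inspection).
    """
    df = table.df
    report = ExclusionReport()
    out_counts = []
    drop_index = pd.Series(False, index=df.index)

    is_nd = df["group"] == "ND"
    for region, sub in df[is_nd].groupby("region"):
        flagged: set[str] = set()
        for method, cell in sub.groupby("method"):
            vals = cell["volume_mm3"].to_numpy()
            mask = detect_outliers(vals, threshold) if len(vals) >= 2 else np.zeros(len(vals), bool)
            ids = cell["subject_id"].to_numpy()[mask]
            out_counts.append({"method": method, "region": region, "n_outliers": int(mask.sum())})
            flagged.update(ids)
        drop_index |= is_nd & (df["region"] == region) & df["subject_id"].isin(flagged)
        report.excluded_subjects[region] = sorted(flagged)
        report.included_n[region] = int(sub.loc[~sub["subject_id"].isin(flagged),
                                                "subject_id"].nunique())

    if "exclude" in df.columns:
        drop_index |= (df["group"] == "AD") & (df["exclude"] == 1)

    report.outliers = pd.DataFrame(out_counts, columns=["method", "region", "n_outliers"])
    out = df[~drop_index]
    log.info("region exclusion (|z| > %g): removed %d records", threshold, int(drop_index.sum()))
    return table.replace_df(out, outlier_threshold=threshold), report
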