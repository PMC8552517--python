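"""End-to-end orchestration of the two analysis scenarios.

Scenario 1 — the same segmentation method produces both the normative
distribution and the patient volumes: fit a normative model per
(method, region) on the reference group, z-score the patients against
their own method's model, then measure between-method absolute agreement
on those z-scores (ICC-z) and each z-score's diagnostic AUC.

Scenario 2 — different methods would produce normative and patient data:
methods must agree on the raw volumes, measured with PCC-v (ordering) and
ICC-v (absolute agreement) on the reference group.

Every run emits a manifest with content hashes of all outputs, so a run is
reproducible bit-for-bit from its configuration and seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import zlib
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .agreement import (AgreementMatrix, compare_method_means, pairwise_matrix,
                        rate_agreement, write_triangle_csv)
from .data_io import CohortTable, RunConfig, write_cohort_table
from .discrimination import auc_with_ci, restrict_age_window
from .normative import FitError, NormativeModel, fit_lms, z_score
from .preprocessing import (ExclusionReport, apply_region_exclusion,
                            exclude_failures, merge_caudate_accumbens,
                            merge_hemispheres)
from .synthetic import REGION_CAUDATE, REGION_CAUDATE_ACCUMBENS

log = logging.getLogger("normvol")


class PipelineError(RuntimeError):
    """A stage failure, carrying the stage name."""

    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _cell_seed(master_seed: int, *parts: str) -> int:
    """Deterministic per-cell seed derived from the master seed."""
    tag = zlib.crc32("/".join(parts).encode())
    return int(np.random.SeedSequence([master_seed, tag]).generate_state(1)[0] % (2**31))


def detect_premerged(table: CohortTable) -> frozenset[str]:
    """Methods that already report caudate+accumbens as one region."""
    df = table.df
    has_merged = set(df.loc[df["region"] == REGION_CAUDATE_ACCUMBENS, "method"])
    has_caudate = set(df.loc[df["region"] == REGION_CAUDATE, "method"])
    return frozenset(has_merged - has_caudate)


def preprocess(table: CohortTable, config: RunConfig
               ) -> tuple[CohortTable, ExclusionReport, ExclusionReport]:
    """Harmonize regions and remove failures and outliers.

    Returns the analysis-ready table plus the failure and outlier reports.
    """
    counts = {"input": len(table.df)}
    try:
        table = merge_hemispheres(table)
        counts["after_hemisphere_merge"] = len(table.df)
        table = merge_caudate_accumbens(table, detect_premerged(table))
        counts["after_caudate_merge"] = len(table.df)
        table, fail_report = exclude_failures(table)
        counts["after_failure_exclusion"] = len(table.df)
        table, outlier_report = apply_region_exclusion(table, config.outlier_threshold)
        counts["after_outlier_exclusion"] = len(table.df)
    except Exception as e:  # noqa: BLE001 - re-raise with stage context
        raise PipelineError("preprocess", e) from e
    table.provenance["stage_counts"] = counts
    if config.methods:
        table = table.replace_df(table.df[table.df["method"].isin(config.methods)])
    if config.regions:
        table = table.replace_df(table.df[table.df["region"].isin(config.regions)])
    return table, fail_report, outlier_report


def volume_summary(table: CohortTable) -> pd.DataFrame:
    """Mean (SD) of reference-group volumes per method x region."""
    nd = table.df[table.df["group"] == "ND"]
    out = (nd.groupby(["method", "region"])["volume_mm3"]
           .agg(mean="mean", sd=lambda v: v.std(ddof=1), n="count")
           .reset_index())
    return out


def fit_normative_models(table: CohortTable, config: RunConfig
                         ) -> dict[tuple[str, str], NormativeModel]:
    """Fit one normative model per (method, region) on the ND group."""
    nd = table.df[table.df["group"] == "ND"]
    models: dict[tuple[str, str], NormativeModel] = {}
    for (method, region), cell in nd.groupby(["method", "region"]):
        try:
            model = fit_lms(
                cell["age"], cell["volume_mm3"], cell["sex"], cell["height"],
                delta=config.delta, min_n=config.min_fit_n,
                method=method, region=region,
            )
        except FitError as e:
            raise PipelineError(f"fit_normative[{method}/{region}]", e) from e
        model.provenance = {
            "outlier_threshold": config.outlier_threshold,
            "n_train": int(len(cell)),
        }
        models[(method, region)] = model
        log.info("fitted %s/%s: n=%d z_mean=%.3f z_sd=%.3f", method, region,
                 model.diagnostics["n"], model.diagnostics["train_z_mean"],
                 model.diagnostics["train_z_sd"])
    return models


def score_group(table: CohortTable, models: dict, group: str) -> pd.DataFrame:
    """z-score every subject of a group against their own method's model."""
    df = table.df[table.df["group"] == group]
    frames = []
    for (method, region), model in models.items():
        cell = df[(df["method"] == method) & (df["region"] == region)]
        if not len(cell):
            continue
        z = z_score(model, cell["age"].to_numpy(), cell["sex"].to_numpy(),
                    cell["height"].to_numpy(), cell["volume_mm3"].to_numpy(),
                    allow_extrapolation=True)
        frames.append(pd.DataFrame({
            "subject_id": cell["subject_id"].to_numpy(),
            "age": cell["age"].to_numpy(),
            "group": group,
            "method": method,
            "region": region,
            "z": z,
        }))
    if not frames:
        return pd.DataFrame(columns=["subject_id", "age", "group", "method", "region", "z"])
    return pd.concat(frames, ignore_index=True)


def cross_method_z(table: CohortTable, models: dict, data_method: str,
                   model_method: str, region: str, group: str = "AD") -> pd.DataFrame:
    """z-scores of one method's volumes under *another* method's model.

    Diagnostic/demonstration output only: it exhibits how a systematic
    offset or scaling between methods shifts patient z-scores when
    normative and patient data come from different methods.
    """
    model = models[(model_method, region)]
    df = table.df
    cell = df[(df["group"] == group) & (df["method"] == data_method)
              & (df["region"] == region)]
    z = z_score(model, cell["age"].to_numpy(), cell["sex"].to_numpy(),
                cell["height"].to_numpy(), cell["volume_mm3"].to_numpy(),
                allow_extrapolation=True)
    return pd.DataFrame({
        "subject_id": cell["subject_id"].to_numpy(),
        "data_method": data_method,
        "model_method": model_method,
        "region": region,
        "z": z,
    })


# ---------------------------------------------------------------------------
# Scenarios


def run_scenario1(table: CohortTable, config: RunConfig,
                  out_dir: str | Path | None = None,
                  preprocessed: bool = False) -> dict:
    """Same-method normative + patient analysis.

    Returns a dict with the preprocessed table, fitted models, AD z-score
    table, per-region ICC-z matrices, per-(method, region) AUC results and
    the ND volume summary.
    """
    if not preprocessed:
        table, fail_report, outlier_report = preprocess(table, config)
    else:
        fail_report = outlier_report = None
    models = fit_normative_models(table, config)
    z_ad = score_group(table, models, "AD")
    z_nd = score_group(table, models, "ND")

    icc_z = {}
    for region in sorted(z_ad["region"].unique()):
        try:
            icc_z[region] = pairwise_matrix(z_ad, "ICC", region=region,
                                            value_col="z", metric_name="ICC-z")
        except ValueError as e:
            raise PipelineError(f"icc_z[{region}]", e) from e

    auc = {}
    windowed_nd = restrict_age_window(z_nd.assign(group="ND"), config.ad_age_window)
    for (method, region), _model in models.items():
        nd_vals = windowed_nd[(windowed_nd["method"] == method)
                              & (windowed_nd["region"] == region)]["z"].to_numpy()
        ad_vals = z_ad[(z_ad["method"] == method)
                       & (z_ad["region"] == region)]["z"].to_numpy()
        if nd_vals.size < 2 or ad_vals.size < 2:
            log.warning("AUC skipped for %s/%s: too few subjects", method, region)
            continue
        auc[(method, region)] = auc_with_ci(
            nd_vals, ad_vals, reps=config.bootstrap_reps,
            seed=_cell_seed(config.seed, "auc", method, region),
        )

    results = {
        "table": table,
        "failure_report": fail_report,
        "outlier_report": outlier_report,
        "models": models,
        "z_ad": z_ad,
        "z_nd": z_nd,
        "icc_z": icc_z,
        "auc": auc,
        "volume_summary": volume_summary(table),
    }
    if out_dir is not None:
        _write_scenario1(results, config, Path(out_dir))
    return results


def run_scenario2(table: CohortTable, config: RunConfig,
                  out_dir: str | Path | None = None,
                  preprocessed: bool = False) -> dict:
    """Between-method assessment on reference volumes: PCC-v and ICC-v per
    region with qualitative ratings, plus the ANOVA/Tukey comparison of
    method means."""
    if not preprocessed:
        table, fail_report, outlier_report = preprocess(table, config)
    else:
        fail_report = outlier_report = None
    nd = table.df[table.df["group"] == "ND"]
    if nd["method"].nunique() < 2:
        raise PipelineError("scenario2", ValueError("need at least 2 methods"))

    pcc_v, icc_v, ratings, anova = {}, {}, [], {}
    for region in sorted(nd["region"].unique()):
        try:
            pcc_v[region] = pairwise_matrix(nd, "PCC", region=region)
            icc_v[region] = pairwise_matrix(nd, "ICC", region=region)
        except ValueError as e:
            raise PipelineError(f"agreement[{region}]", e) from e
        for mat in (pcc_v[region], icc_v[region]):
            for _, row in mat.to_long().iterrows():
                if np.isfinite(row["value"]):
                    ratings.append({"region": region, "metric": mat.metric,
                                    "method_a": row["method_a"], "method_b": row["method_b"],
                                    "value": row["value"],
                                    "rating": rate_agreement(row["value"])})
        groups = {m: g["volume_mm3"].to_numpy()
                  for m, g in nd[nd["region"] == region].groupby("method")}
        if len(groups) >= 2 and all(v.size >= 2 for v in groups.values()):
            anova[region] = compare_method_means(groups)

    results = {
        "table": table,
        "failure_report": fail_report,
        "outlier_report": outlier_report,
        "pcc_v": pcc_v,
        "icc_v": icc_v,
        "ratings": pd.DataFrame(ratings),
        "anova": anova,
        "volume_summary": volume_summary(table),
    }
    if out_dir is not None:
        _write_scenario2(results, config, Path(out_dir))
    return results


def run_all(table: CohortTable, config: RunConfig, out_dir: str | Path) -> dict:
    """Full analysis: preprocessing once, then both scenarios, one manifest."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    prepped, fail_report, outlier_report = preprocess(table, config)
    s2 = run_scenario2(prepped, config, preprocessed=True)
    s1 = run_scenario1(prepped, config, preprocessed=True)
    s1["failure_report"] = s2["failure_report"] = fail_report
    s1["outlier_report"] = s2["outlier_report"] = outlier_report

    write_cohort_table(table, out_dir / "cohort.csv")
    _write_exclusions(fail_report, outlier_report, prepped, out_dir)
    _write_scenario2(s2, config, out_dir)
    _write_scenario1(s1, config, out_dir)
    manifest = write_manifest(out_dir, config, table, prepped)
    return {"scenario1": s1, "scenario2": s2, "manifest": manifest,
            "failure_report": fail_report, "outlier_report": outlier_report}


# ---------------------------------------------------------------------------
# Output writers


def _fmt_float(df: pd.DataFrame) -> pd.DataFrame:
    return df.round(6)


def _write_exclusions(fail_report, outlier_report, table: CohortTable, out_dir: Path) -> None:
    methods = sorted(table.df["method"].unique())
    if outlier_report is not None:
        outlier_report.to_table(methods).to_csv(out_dir / "exclusions.csv", index=False)
    if fail_report is not None and len(fail_report.failures):
        fail_report.failures.to_csv(out_dir / "failures.csv", index=False)


def _write_scenario1(results: dict, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    model_dir = out_dir / "models"
    model_dir.mkdir(exist_ok=True)
    for (method, region), model in results["models"].items():
        model.save(model_dir / f"{method}__{region}.json")
    _fmt_float(results["z_ad"]).to_csv(out_dir / "zscores_ad.csv", index=False)
    for region, mat in results["icc_z"].items():
        _fmt_float(mat.values).to_csv(out_dir / f"icc_z_{region}.csv")
        mat.to_long().to_csv(out_dir / f"icc_z_{region}_long.csv", index=False)
    rows = []
    for (method, region), res in results["auc"].items():
        rows.append({"region": region, "method": method, "auc": res.auc,
                     "ci_low": res.ci_low, "ci_high": res.ci_high,
                     "n_nd": res.n_nd, "n_ad": res.n_ad})
    auc_long = pd.DataFrame(rows)
    _fmt_float(auc_long).to_csv(out_dir / "auc_long.csv", index=False)
    if len(auc_long):
        wide = auc_long.assign(
            cell=[f"{r.auc:.2f} ({r.ci_low:.2f}, {r.ci_high:.2f})"
                  for r in auc_long.itertuples()]
        ).pivot(index="region", columns="method", values="cell")
        wide.to_csv(out_dir / "auc.csv")
    _fmt_float(results["volume_summary"]).to_csv(out_dir / "volume_summary.csv", index=False)


def _write_scenario2(results: dict, config: RunConfig, out_dir: Path) -> None:
    out_dir.mkdir(parents=True, exist_ok=True)
    for region in results["pcc_v"]:
        write_triangle_csv(results["pcc_v"][region], results["icc_v"][region],
                           out_dir / f"agreement_{region}.csv")
        pd.concat([results["pcc_v"][region].to_long(),
                   results["icc_v"][region].to_long()],
                  ignore_index=True).to_csv(out_dir / f"agreement_{region}_long.csv",
                                            index=False)
    if len(results["ratings"]):
        _fmt_float(results["ratings"]).to_csv(out_dir / "ratings.csv", index=False)
    rows = []
    for region, cmp_res in results["anova"].items():
        rows.append({"region": region, "f_statistic": cmp_res.f_statistic,
                     "p_value": cmp_res.p_value})
    if rows:
        _fmt_float(pd.DataFrame(rows)).to_csv(out_dir / "anova.csv", index=False)
        pd.concat([res.tukey.assign(region=region)
                   for region, res in results["anova"].items()],
                  ignore_index=True).to_csv(out_dir / "tukey.csv", index=False)


def write_manifest(out_dir: Path, config: RunConfig, table: CohortTable,
                   prepped: CohortTable) -> dict:
    """Write manifest.json: config snapshot, input hash, stage counts and a
    content hash of every emitted file."""
    outputs = {}
    for path in sorted(out_dir.rglob("*")):
        if path.is_file() and path.name != "manifest.json":
            outputs[str(path.relative_to(out_dir))] = _sha256(path)
    manifest = {
        "version": __version__,
        "seed": config.seed,
        "config": dataclasses.asdict(config),
        "input": {
            "provenance": {k: v for k, v in table.provenance.items()
                           if isinstance(v, (str, int, float))},
            "n_rows": len(table.df),
        },
        "stage_counts": prepped.provenance.get("stage_counts", {}),
        "outputs": outputs,
    }
    with open(out_dir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest
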