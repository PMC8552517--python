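"""Reading and writing cohort volume tables and run configuration.

The pipeline operates on long-format tables with one row per
subject x method x region x hemisphere.  A missing or zero volume marks a
failed segmentation for that cell; failed cells are carried through as NaN
so that exclusion accounting stays explicit.
"""

from __future__ import annotations

import dataclasses
import logging
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import yaml

log = logging.getLogger("normvol")

#: canonical column order of a cohort CSV/TSV
COLUMNS = (
    "subject_id",
    "age",
    "sex",
    "height",
    "group",
    "method",
    "region",
    "hemisphere",
    "volume_mm3",
)
#: optional columns that are preserved when present
OPTIONAL_COLUMNS = ("exclude",)

NUMERIC_COLUMNS = ("age", "sex", "height", "volume_mm3")
GROUPS = ("ND", "AD")
HEMISPHERES = ("left", "right", "both")


class FormatError(ValueError):
    """Raised when an input file violates the cohort-table format."""


class ConfigError(ValueError):
    """Raised when a run-configuration file has unknown or invalid keys."""


@dataclasses.dataclass
class CohortTable:
    """A validated long-format table of regional volume measurements.

    Attributes
    ----------
    df : pandas.DataFrame
        Columns as in :data:`COLUMNS` (plus optional ``exclude``); one row
        per subject x method x region x hemisphere.  ``volume_mm3`` is NaN
        for failed segmentations.
    provenance : dict
        Free-form metadata (source path, generator seed, rejection counts).
    """

    df: pd.DataFrame
    provenance: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        df = self.df
        missing = [c for c in COLUMNS if c not in df.columns]
        if missing:
            raise FormatError(f"cohort table missing required columns: {missing}")
        if len(df):
            bad_group = set(df["group"].unique()) - set(GROUPS)
            if bad_group:
                raise FormatError(f"unknown group labels {sorted(bad_group)}; expected {GROUPS}")
            bad_hemi = set(df["hemisphere"].unique()) - set(HEMISPHERES)
            if bad_hemi:
                raise FormatError(
                    f"unknown hemisphere labels {sorted(bad_hemi)}; expected {HEMISPHERES}"
                )
            if (df["age"] <= 0).any():
                raise FormatError("ages must be positive")
            if (df["height"] <= 0).any():
                raise FormatError("heights must be positive")
            if not df["sex"].isin([0, 1]).all():
                raise FormatError("sex must be coded 0 (female) / 1 (male)")
            vols = df["volume_mm3"]
            if (vols.dropna() < 0).any():
                raise FormatError("volumes must be non-negative")
            key = ["subject_id", "method", "region", "hemisphere"]
            if df.duplicated(subset=key).any():
                dupes = df[df.duplicated(subset=key, keep=False)].head(4)
                raise FormatError(
                    "duplicate (subject, method, region, hemisphere) rows, e.g.\n"
                    + dupes.to_string()
                )

    # -- convenience accessors -------------------------------------------
    @property
    def methods(self) -> list[str]:
        return sorted(self.df["method"].unique())

    @property
    def regions(self) -> list[str]:
        return sorted(self.df["region"].unique())

    def subset(self, **kwargs) -> pd.DataFrame:
        """Return rows matching the given column=value filters."""
        df = self.df
        for col, val in kwargs.items():
            df = df[df[col] == val]
        return df

    def replace_df(self, df: pd.DataFrame, **extra_provenance) -> "CohortTable":
        prov = dict(self.provenance)
        prov.update(extra_provenance)
        return CohortTable(df.reset_index(drop=True), prov)


def _delimiter_for(path: Path, delimiter: str | None) -> str:
    if delimiter is not None:
        return delimiter
    return "\t" if path.suffix.lower() == ".tsv" else ","


def read_cohort_table(path: str | Path, delimiter: str | None = None) -> CohortTable:
    """Read a cohort CSV/TSV into a validated :class:`CohortTable`.

    Column matching is case-insensitive.  Rows whose demographic fields fail
    to parse are rejected (never silently dropped: the counts land in
    ``provenance``, the per-row messages in ``provenance['diagnostics']``).
    An empty or unparsable volume cell becomes a failed record (NaN); an
    unparsable non-empty one rejects the row.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    sep = _delimiter_for(path, delimiter)
    try:
        raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    except pd.errors.EmptyDataError:
        raise FormatError(f"{path}: file is empty") from None
    raw.columns = [c.strip().lower() for c in raw.columns]
    missing = [c for c in COLUMNS if c not in raw.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")

    n_input = len(raw)
    diagnostics: list[str] = []
    keep = np.ones(n_input, dtype=bool)
    parsed = pd.DataFrame(index=raw.index)
    parsed["subject_id"] = raw["subject_id"].str.strip()
    for col in ("group", "method", "region", "hemisphere"):
        parsed[col] = raw[col].str.strip()

    for col in ("age", "sex", "height"):
        vals = pd.to_numeric(raw[col].str.strip(), errors="coerce")
        bad = vals.isna()
        for i in raw.index[bad & keep]:
            diagnostics.append(f"row {i + 2}: unparsable {col} {raw.at[i, col]!r}")
        keep &= ~bad.to_numpy()
        parsed[col] = vals

    vol_raw = raw["volume_mm3"].str.strip()
    vol = pd.to_numeric(vol_raw, errors="coerce")
    empty = vol_raw.isin(["", "NA", "nan", "NaN"])
    bad_vol = vol.isna() & ~empty
    for i in raw.index[bad_vol & keep]:
        diagnostics.append(f"row {i + 2}: unparsable volume_mm3 {vol_raw[i]!r}")
    keep &= ~bad_vol.to_numpy()
    # zero volume == failed segmentation, same as missing
    vol = vol.where(~empty & (vol != 0.0), np.nan)
    parsed["volume_mm3"] = vol

    if "exclude" in raw.columns:
        parsed["exclude"] = pd.to_numeric(raw["exclude"].str.strip(), errors="coerce").fillna(0).astype(int)

    df = parsed[keep].reset_index(drop=True)
    for msg in diagnostics:
        log.warning("%s: %s", path.name, msg)
    table = CohortTable(
        df,
        provenance={
            "source": str(path),
            "n_input_rows": n_input,
            "n_loaded": len(df),
            "n_rejected": n_input - len(df),
            "diagnostics": diagnostics,
        },
    )
    return table


def write_cohort_table(table: CohortTable, path: str | Path, delimiter: str | None = None) -> None:
    """Write a cohort table as CSV/TSV with the canonical column order.

    Floats are serialized with ``repr`` precision, so reading the file back
    reproduces every representable value bit-for-bit.
    """
    path = Path(path)
    sep = _delimiter_for(path, delimiter)
    cols = list(COLUMNS) + [c for c in OPTIONAL_COLUMNS if c in table.df.columns]
    df = table.df.loc[:, cols]
    df.to_csv(path, sep=sep, index=False)


# ---------------------------------------------------------------------------
# Run configuration


@dataclasses.dataclass
class RunConfig:
    """Analysis settings; defaults follow the study protocol.

    outlier_threshold
        Population |z| above which an ND volume is excluded (default 5.0).
    delta
        Smoothness (degrees of freedom) of each normative curve (default 2,
        i.e. linear in age; see :mod:`normvol.normative`).
    bootstrap_reps
        Bootstrap resamples for the AUC confidence interval (default 1000).
    ad_age_window
        Closed age interval of patients; ND subjects outside it are dropped
        from the AUC computation (default [71, 91] years).
    """

    outlier_threshold: float = 5.0
    delta: int = 2
    bootstrap_reps: int = 1000
    ad_age_window: tuple[float, float] = (71.0, 91.0)
    seed: int = 0
    regions: list[str] | None = None
    methods: list[str] | None = None
    min_fit_n: int = 50

    def __post_init__(self) -> None:
        if self.outlier_threshold <= 0:
            raise ConfigError("outlier_threshold must be positive")
        if self.delta < 1:
            raise ConfigError("delta must be >= 1")
        if self.bootstrap_reps < 1:
            raise ConfigError("bootstrap_reps must be >= 1")
        lo, hi = self.ad_age_window
        if not lo < hi:
            raise ConfigError("ad_age_window must be a non-degenerate [low, high]")

    @classmethod
    def valid_keys(cls) -> list[str]:
        return [f.name for f in dataclasses.fields(cls)]


def read_run_config(path: str | Path) -> RunConfig:
    """Load a flat key-value (YAML) run configuration.

    Unspecified keys take the protocol defaults; an unknown key fails fast
    with the list of valid keys (typos never silently alter a run).
    """
    path = Path(path)
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        doc = {}
    if not isinstance(doc, dict):
        raise ConfigError(f"{path}: expected a flat key-value document")
    valid = RunConfig.valid_keys()
    unknown = [k for k in doc if k not in valid]
    if unknown:
        raise ConfigError(
            f"{path}: unknown key(s) {unknown}; valid keys are {valid}"
        )
    if "ad_age_window" in doc:
        doc["ad_age_window"] = tuple(float(v) for v in doc["ad_age_window"])
    return RunConfig(**doc)
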