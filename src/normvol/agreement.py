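"""Between-method correlation and absolute agreement.

Two methods measuring the same subjects form an n x k matrix X (rows =
subjects, columns = methods).  The Pearson correlation (PCC-v) captures
ordering only; the single-rater absolute-agreement intraclass correlation
ICC(A,1) from the two-way ANOVA decomposition additionally penalizes
offsets and scalings:

    ICC(A,1) = (MSR - MSE) / (MSR + (k-1) MSE + (k/n)(MSC - MSE))

with MSR, MSC, MSE the mean squares for rows, columns and error.  ICC is
1.0 exactly when all columns are identical; a systematic offset of one
population SD on one of two columns drives it to ~2/3, a scaling of 1.2 at
mean/SD = 5/1 to ~0.7.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger("normvol")

RATING_LABELS = ("poor", "fair", "good", "excellent")


class UndefinedStatisticError(ValueError):
    """Raised when a statistic has no defined value (e.g. constant input)."""


@dataclasses.dataclass
class MeanSquares:
    """Two-way mean squares of a measurement matrix."""

    msr: float
    msc: float
    mse: float
    n: int
    k: int


def _as_matrix(X) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    if X.ndim != 2:
        raise ValueError("expected a 2-D subjects x methods matrix")
    n, k = X.shape
    if n < 2 or k < 2:
        raise ValueError(f"need at least 2 subjects and 2 methods, got {n} x {k}")
    if not np.isfinite(X).all():
        raise ValueError("measurement matrix must be complete (no missing cells)")
    return X


def mean_squares(X) -> MeanSquares:
    """Mean squares for rows, columns and error of a subjects x methods
    matrix (two-way decomposition; SS_total = SS_rows + SS_cols + SS_err)."""
    X = _as_matrix(X)
    n, k = X.shape
    row_means = X.mean(axis=1)
    col_means = X.mean(axis=0)
    grand = X.mean()
    msr = k * np.sum((row_means - grand) ** 2) / (n - 1)
    msc = n * np.sum((col_means - grand) ** 2) / (k - 1)
    resid = X - row_means[:, None] - col_means[None, :] + grand
    mse = np.sum(resid ** 2) / ((n - 1) * (k - 1))
    return MeanSquares(float(msr), float(msc), float(mse), n, k)


def icc_a1(X) -> float:
    """Absolute-agreement intraclass correlation ICC(A,1).

    Raises :class:`UndefinedStatisticError` on a fully constant matrix
    (zero denominator) — an undefined agreement is never reported as a
    number.
    """
    ms = mean_squares(X)
    denom = ms.msr + (ms.k - 1) * ms.mse + (ms.k / ms.n) * (ms.msc - ms.mse)
    if denom == 0.0:
        raise UndefinedStatisticError("ICC(A,1) undefined: constant measurement matrix")
    return float((ms.msr - ms.mse) / denom)


def pearson_corr(x, y) -> float:
    """Pearson product-moment correlation of two equal-length sequences."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be 1-D sequences of equal length")
    if x.size < 2:
        raise ValueError("need at least 2 observations")
    if np.std(x) == 0.0 or np.std(y) == 0.0:
        raise UndefinedStatisticError("Pearson correlation undefined for constant input")
    return float(stats.pearsonr(x, y).statistic)


@dataclasses.dataclass
class AgreementMatrix:
    """Symmetric method x method table of pairwise agreement values."""

    metric: str  # "PCC-v" | "ICC-v" | "ICC-z"
    labels: list[str]
    values: pd.DataFrame  # k x k, unit diagonal, NaN where unavailable
    n_used: pd.DataFrame  # per-cell complete-case subject count

    def to_frame(self) -> pd.DataFrame:
        return self.values.copy()

    def to_long(self) -> pd.DataFrame:
        """Tidy long-format variant (one row per unordered method pair)."""
        rows = []
        for i, a in enumerate(self.labels):
            for j, b in enumerate(self.labels):
                if j <= i:
                    continue
                rows.append({"method_a": a, "method_b": b, "metric": self.metric,
                             "value": self.values.iloc[i, j],
                             "n": self.n_used.iloc[i, j]})
        return pd.DataFrame(rows)


def pairwise_matrix(df: pd.DataFrame, metric: str, region: str | None = None,
                    value_col: str = "volume_mm3",
                    metric_name: str | None = None) -> AgreementMatrix:
    """Pairwise agreement matrix over methods from a long-format table.

    Each cell is computed on the complete-case subject set of that method
    pair (pairwise deletion); the subject count enters ``n_used``.  Cells
    with insufficient overlap or undefined statistics stay NaN.

    Parameters
    ----------
    df : long-format DataFrame with columns subject_id, method, ``value_col``
        (and region, if ``region`` is given).
    metric : "PCC" or "ICC".
    """
    if metric not in ("PCC", "ICC"):
        raise ValueError("metric must be 'PCC' or 'ICC'")
    if region is not None:
        df = df[df["region"] == region]
    wide = df.pivot_table(index="subject_id", columns="method",
                          values=value_col, aggfunc="first")
    labels = sorted(wide.columns)
    k = len(labels)
    if k < 2:
        raise ValueError("need at least 2 methods")
    vals = pd.DataFrame(np.eye(k), index=labels, columns=labels)
    ns = pd.DataFrame(0, index=labels, columns=labels, dtype=int)
    for i in range(k):
        ns.iloc[i, i] = int(wide[labels[i]].notna().sum())
    for i in range(k):
        for j in range(i + 1, k):
            pair = wide[[labels[i], labels[j]]].dropna()
            ns.iloc[i, j] = ns.iloc[j, i] = len(pair)
            if len(pair) < 2:
                vals.iloc[i, j] = vals.iloc[j, i] = np.nan
                continue
            try:
                if metric == "PCC":
                    v = pearson_corr(pair.iloc[:, 0], pair.iloc[:, 1])
                else:
                    v = icc_a1(pair.to_numpy())
            except UndefinedStatisticError:
                v = np.nan
            vals.iloc[i, j] = vals.iloc[j, i] = v
    name = metric_name or {"PCC": "PCC-v", "ICC": "ICC-v"}[metric]
    return AgreementMatrix(metric=name, labels=labels, values=vals, n_used=ns)


def rate_agreement(value: float) -> str:
    """Qualitative rating of an agreement value.

    Bands are closed on the left: < 0.5 poor, [0.5, 0.7) fair,
    [0.7, 0.9) good, >= 0.9 excellent.
    """
    if not np.isfinite(value):
        raise ValueError("cannot rate a non-finite value")
    if value < 0.5:
        return "poor"
    if value < 0.7:
        return "fair"
    if value < 0.9:
        return "good"
    return "excellent"


@dataclasses.dataclass
class MethodMeansComparison:
    """One-way ANOVA of method means with Tukey HSD post hoc tests."""

    f_statistic: float
    p_value: float
    tukey: pd.DataFrame  # method_a, method_b, p_adjusted


def compare_method_means(groups: dict[str, np.ndarray]) -> MethodMeansComparison:
    """One-way fixed-effects ANOVA across methods plus Tukey-adjusted
    pairwise p-values.

    ``groups`` maps method label -> 1-D array of volumes.
    """
    labels = sorted(groups)
    arrays = [np.asarray(groups[m], dtype=float) for m in labels]
    if len(arrays) < 2 or any(a.size < 2 for a in arrays):
        raise ValueError("need >= 2 groups with >= 2 values each")
    f_stat, p = stats.f_oneway(*arrays)
    res = stats.tukey_hsd(*arrays)
    rows = []
    for i in range(len(labels)):
        for j in range(i + 1, len(labels)):
            rows.append({"method_a": labels[i], "method_b": labels[j],
                         "p_adjusted": float(res.pvalue[i, j])})
    return MethodMeansComparison(float(f_stat), float(p), pd.DataFrame(rows))


def write_triangle_csv(upper: AgreementMatrix, lower: AgreementMatrix, path) -> None:
    """Combined table with one metric in the upper-right triangle and
    another in the lower-left (the study's compact presentation)."""
    if upper.labels != lower.labels:
        raise ValueError("matrices must share method labels")
    labels = upper.labels
    k = len(labels)
    out = pd.DataFrame("", index=labels, columns=labels, dtype=object)
    for i in range(k):
        out.iloc[i, i] = "1.00"
        for j in range(i + 1, k):
            u, l = upper.values.iloc[i, j], lower.values.iloc[i, j]
            out.iloc[i, j] = "" if np.isnan(u) else f"{u:.2f}"
            out.iloc[j, i] = "" if np.isnan(l) else f"{l:.2f}"
    out.index.name = f"{lower.metric} \\ {upper.metric}"
    out.to_csv(path)
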