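"""Diagnostic value of normative z-scores.

Patients are expected to sit below the reference distribution, so
discrimination is summarized as the probability that a randomly chosen
reference (ND) subject has a *higher* z-score than a randomly chosen
patient (AD):

    AUC = (1 / (n_nd * n_ad)) * sum over pairs [ 1{z_nd > z_ad} + 0.5 * 1{tie} ]

which is the Mann-Whitney U statistic normalized by the number of pairs.
Only reference subjects inside the patients' age window enter, and a 95%
percentile confidence interval comes from a stratified bootstrap.
"""

from __future__ import annotations

import dataclasses
import logging

import numpy as np
import pandas as pd
from scipy.stats import rankdata

log = logging.getLogger("normvol")

DEFAULT_BOOTSTRAP_REPS = 1000
DEFAULT_AGE_WINDOW = (71.0, 91.0)


@dataclasses.dataclass
class AUCResult:
    """AUC of the z-score with its bootstrap confidence interval."""

    auc: float
    ci_low: float
    ci_high: float
    n_nd: int
    n_ad: int
    bootstrap_reps: int
    seed: int | None


def auc_z(z_nd, z_ad) -> float:
    """P(random ND z-score > random AD z-score), ties counting one half.

    Computed from midranks, so it equals the normalized Mann-Whitney U
    statistic exactly, including the tie rule.
    """
    z_nd = np.asarray(z_nd, dtype=float)
    z_ad = np.asarray(z_ad, dtype=float)
    if z_nd.size == 0 or z_ad.size == 0:
        raise ValueError("both groups must be non-empty")
    pooled = np.concatenate([z_nd, z_ad])
    ranks = rankdata(pooled)  # midranks give the 0.5 tie credit
    r_nd = ranks[: z_nd.size].sum()
    u = r_nd - z_nd.size * (z_nd.size + 1) / 2.0
    return float(u / (z_nd.size * z_ad.size))


def restrict_age_window(df: pd.DataFrame,
                        window: tuple[float, float] = DEFAULT_AGE_WINDOW) -> pd.DataFrame:
    """Keep ND rows whose age lies in the closed window; AD rows always pass.

    ``df`` needs columns ``group`` and ``age``.
    """
    lo, hi = window
    if not lo < hi:
        raise ValueError("age window must be non-degenerate [low, high]")
    is_ad = df["group"] == "AD"
    in_window = (df["age"] >= lo) & (df["age"] <= hi)
    return df[is_ad | in_window]


def bootstrap_auc_ci(z_nd, z_ad, reps: int = DEFAULT_BOOTSTRAP_REPS,
                     seed: int | None = None,
                     rng: np.random.Generator | None = None) -> tuple[float, float]:
    """95% percentile bootstrap interval for the AUC.

    Resampling is stratified: each replicate draws with replacement within
    the ND and AD groups independently, preserving both group sizes.
    """
    z_nd = np.asarray(z_nd, dtype=float)
    z_ad = np.asarray(z_ad, dtype=float)
    if z_nd.size < 2 or z_ad.size < 2:
        raise ValueError("both groups need >= 2 values for a bootstrap interval")
    if rng is None:
        rng = np.random.default_rng(seed)
    aucs = np.empty(reps)
    for r in range(reps):
        bs_nd = z_nd[rng.integers(0, z_nd.size, z_nd.size)]
        bs_ad = z_ad[rng.integers(0, z_ad.size, z_ad.size)]
        aucs[r] = auc_z(bs_nd, bs_ad)
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)


def auc_with_ci(z_nd, z_ad, reps: int = DEFAULT_BOOTSTRAP_REPS,
                seed: int | None = None) -> AUCResult:
    """Point AUC plus stratified-bootstrap 95% CI in one call."""
    point = auc_z(z_nd, z_ad)
    lo, hi = bootstrap_auc_ci(z_nd, z_ad, reps=reps, seed=seed)
    return AUCResult(auc=point, ci_low=lo, ci_high=hi,
                     n_nd=int(np.size(z_nd)), n_ad=int(np.size(z_ad)),
                     bootstrap_reps=reps, seed=seed)
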