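"""Independent brute-force oracles used to validate the implementation.

Everything here is written from first principles (explicit loops, direct
definitions) and deliberately shares no code with the package.
"""

from __future__ import annotations

import numpy as np


def anova_two_way_oracle(X):
    """Two-way (subjects x methods, one observation per cell) mean squares
    via explicit sums of squares."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    grand = sum(X[i, j] for i in range(n) for j in range(k)) / (n * k)
    row_means = [sum(X[i, j] for j in range(k)) / k for i in range(n)]
    col_means = [sum(X[i, j] for i in range(n)) / n for j in range(k)]
    ss_rows = k * sum((rm - grand) ** 2 for rm in row_means)
    ss_cols = n * sum((cm - grand) ** 2 for cm in col_means)
    ss_total = sum((X[i, j] - grand) ** 2 for i in range(n) for j in range(k))
    ss_err = ss_total - ss_rows - ss_cols
    msr = ss_rows / (n - 1)
    msc = ss_cols / (k - 1)
    mse = ss_err / ((n - 1) * (k - 1))
    return msr, msc, mse


def icc_a1_oracle(X):
    """ICC(A,1) assembled from the brute-force ANOVA table."""
    X = np.asarray(X, dtype=float)
    n, k = X.shape
    msr, msc, mse = anova_two_way_oracle(X)
    return (msr - mse) / (msr + (k - 1) * mse + (k / n) * (msc - mse))


def oneway_f_oracle(groups):
    """One-way fixed-effects ANOVA F statistic via the two-step SS
    decomposition."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    all_vals = np.concatenate(groups)
    grand = sum(float(v) for v in all_vals) / all_vals.size
    ss_between = sum(g.size * (sum(map(float, g)) / g.size - grand) ** 2 for g in groups)
    ss_within = sum(sum((float(v) - sum(map(float, g)) / g.size) ** 2 for v in g)
                    for g in groups)
    df_between = len(groups) - 1
    df_within = all_vals.size - len(groups)
    return (ss_between / df_between) / (ss_within / df_within)


def auc_pairs_oracle(z_nd, z_ad):
    """AUC by enumerating every (ND, AD) pair with the half-credit tie rule."""
    total = 0.0
    for a in z_nd:
        for b in z_ad:
            if a > b:
                total += 1.0
            elif a == b:
                total += 0.5
    return total / (len(z_nd) * len(z_ad))
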