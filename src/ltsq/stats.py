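"""Correlation and rank-test utilities for cohort evaluation.

These are the statistics used to relate image features to expert scores
and clinical measures: Spearman and Pearson correlations, the
Wilcoxon–Mann–Whitney rank-sum test (two groups) and the Kruskal–Wallis
test (k groups).  All tests are two-sided.  The Mann–Whitney statistic is
reported as U = min(U_a, U_b); for combined sample sizes ≤ 12 the p-value
is computed by exact enumeration of group assignments (ties included),
otherwise by the tie-corrected normal approximation with continuity
correction.
"""

from __future__ import annotations

from itertools import combinations
from math import comb

import numpy as np
from scipy import stats as sps

from .errors import ValidationError

#: Combined sample size at or below which the exact Mann–Whitney
#: enumeration replaces the normal approximation.
EXACT_LIMIT = 12


def spearman_rho(x, y) -> tuple[float, float]:
    """Spearman rank correlation (ties mid-ranked) with two-sided p."""
    x, y = _paired(x, y)
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def pearson_r(x, y) -> tuple[float, float]:
    """Pearson product-moment correlation with two-sided t-based p."""
    x, y = _paired(x, y)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def _paired(x, y):
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValidationError("paired series must have equal length")
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3:
        raise ValidationError("correlations need at least 3 complete pairs")
    return x, y


def _u_min(values: np.ndarray, a_idx: np.ndarray, n_a: int, n_b: int) -> float:
    ranks = sps.rankdata(values)
    r_a = ranks[a_idx].sum()
    u_a = r_a - n_a * (n_a + 1) / 2
    return min(u_a, n_a * n_b - u_a)


def mann_whitney_u(group_a, group_b) -> tuple[float, float]:
    """Two-sided Wilcoxon–Mann–Whitney rank-sum test.

    Returns (U, p) with U = min(U_a, U_b).  Exact enumeration over all
    C(n_a+n_b, n_a) group assignments when n_a + n_b ≤ 12 (valid under
    ties); tie-corrected normal approximation with continuity correction
    otherwise.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValidationError("both groups must be non-empty")
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    u_obs = _u_min(pooled, np.arange(n_a), n_a, n_b)

    n = n_a + n_b
    if n <= EXACT_LIMIT:
        count = 0
        for a_pos in combinations(range(n), n_a):
            if _u_min(pooled, np.array(a_pos), n_a, n_b) <= u_obs + 1e-9:
                count += 1
        p = count / comb(n, n_a)
        return float(u_obs), float(min(1.0, p))

    ranks = sps.rankdata(pooled)
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts))
    mu = n_a * n_b / 2
    var = n_a * n_b / 12 * ((n + 1) - tie_term / (n * (n - 1)))
    if var <= 0:
        return float(u_obs), float("nan")
    z = (u_obs - mu + 0.5) / np.sqrt(var)
    p = 2 * sps.norm.cdf(z)
    return float(u_obs), float(min(1.0, p))


def kruskal_wallis(groups) -> tuple[float, float]:
    """Tie-corrected Kruskal–Wallis H with chi-square p (k−1 df).

    When every pooled value is identical the statistic degenerates (the
    tie correction divides by zero); H = 0 and p = NaN are returned as the
    all-ties flag.
    """
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2 or any(len(g) == 0 for g in groups):
        raise ValidationError("need at least 2 non-empty groups")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    h = 0.0
    start = 0
    for g in groups:
        r = ranks[start : start + len(g)].sum()
        h += r * r / len(g)
        start += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    _, tie_counts = np.unique(pooled, return_counts=True)
    correction = 1 - float(np.sum(tie_counts**3 - tie_counts)) / (n**3 - n)
    if correction == 0:
        return 0.0, float("nan")
    h /= correction
    df = len(groups) - 1
    return float(h), float(sps.chi2.sf(h, df))
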