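"""Shared statistical helpers (BH adjustment, rank-sum dispatch)."""

from __future__ import annotations

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

#: largest per-group size for which the exact rank-sum null is used
EXACT_RANKSUM_MAX_N = 25


def bh_adjust(pvalues: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values (order-independent)."""
    pvalues = np.asarray(pvalues, dtype=float)
    if pvalues.size == 0:
        return pvalues.copy()
    return multipletests(pvalues, method="fdr_bh")[1]


def _has_ties(x: np.ndarray, y: np.ndarray) -> bool:
    pooled = np.concatenate([x, y])
    return np.unique(pooled).size < pooled.size


def rank_sum_test(
    x: np.ndarray, y: np.ndarray, alternative: str = "two-sided"
) -> tuple[float, float]:
    """Mann-Whitney/Wilcoxon rank-sum test with explicit method dispatch.

    Exact null distribution when both groups have <= EXACT_RANKSUM_MAX_N
    observations and there are no ties; otherwise the normal approximation
    with continuity and tie correction.

    Returns (U statistic of ``x``, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    exact = (
        max(x.size, y.size) <= EXACT_RANKSUM_MAX_N and not _has_ties(x, y)
    )
    res = stats.mannwhitneyu(
        x, y, alternative=alternative, method="exact" if exact else "asymptotic"
    )
    return float(res.statistic), float(res.pvalue)


def rank_sum_test_matrix(
    a: np.ndarray, b: np.ndarray, alternative: str = "two-sided"
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise rank-sum tests for matrices ``a`` (m x n1) and ``b`` (m x n2).

    Rows without ties use the exact null (if group sizes permit); tied rows
    fall back to the tie-corrected normal approximation.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    m = a.shape[0]
    stat = np.empty(m)
    pval = np.empty(m)

    pooled = np.sort(np.concatenate([a, b], axis=1), axis=1)
    tied_rows = (np.diff(pooled, axis=1) == 0).any(axis=1)
    size_ok = max(a.shape[1], b.shape[1]) <= EXACT_RANKSUM_MAX_N

    exact_mask = (~tied_rows) & size_ok
    if exact_mask.any():
        res = stats.mannwhitneyu(
            a[exact_mask], b[exact_mask], alternative=alternative,
            method="exact", axis=1,
        )
        stat[exact_mask] = res.statistic
        pval[exact_mask] = res.pvalue
    rest = ~exact_mask
    if rest.any():
        res = stats.mannwhitneyu(
            a[rest], b[rest], alternative=alternative,
            method="asymptotic", axis=1,
        )
        stat[rest] = res.statistic
        pval[rest] = res.pvalue
    return stat, np.clip(pval, 0.0, 1.0)
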