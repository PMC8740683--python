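"""Shared statistical helpers: exact tests, Fisher's method, BH FDR."""
from __future__ import annotations

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests


def fisher_exact_greater(a: int, group1: int, group2: int, k: int) -> float:
    """One-sided Fisher exact p-value for enrichment in group 1.

    ``a`` of the ``k`` marked individuals fall in group 1 (size ``group1``);
    the remaining ``k - a`` fall in group 2 (size ``group2``). Returns
    P(X >= a) under the hypergeometric null with those margins.
    """
    n_total = group1 + group2
    return float(sps.hypergeom.sf(a - 1, n_total, k, group1))


def fisher_exact_greater_vec(a, group1: int, group2: int, k) -> np.ndarray:
    """Vectorized :func:`fisher_exact_greater` over arrays ``a`` and ``k``."""
    a = np.asarray(a)
    k = np.asarray(k)
    return sps.hypergeom.sf(a - 1, group1 + group2, k, group1)


def fisher_method(pvalues) -> tuple[float, float]:
    """Combine independent p-values: X = -2 sum(ln p) ~ chi2 on 2k df.

    Returns ``(statistic, combined_p)``. p-values are clipped away from 0
    at 1e-300 to keep the log finite.
    """
    p = np.clip(np.asarray(pvalues, dtype=float), 1e-300, 1.0)
    if p.size == 0:
        raise ValueError("fisher_method needs at least one p-value")
    x = -2.0 * np.log(p).sum()
    return float(x), float(sps.chi2.sf(x, 2 * p.size))


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted q-values."""
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]


def wilcoxon_rank_sum(x, y) -> float:
    """Two-sided Wilcoxon rank-sum (Mann-Whitney U) p-value.

    Exact when sample sizes are small and tie-free (scipy's automatic
    policy); normal approximation with tie correction otherwise.
    """
    res = sps.mannwhitneyu(x, y, alternative="two-sided", method="auto")
    return float(res.pvalue)
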