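"""Shared statistical primitives: rank-sum tests with exact small-sample
enumeration, two-sided binomial tail doubling, and FDR adjustment.

The Wilcoxon rank-sum test uses exact enumeration of rank assignments when
both groups have at most 8 observations (cached null distribution when there
are no ties, full enumeration of index subsets otherwise) and the mid-rank
normal approximation with tie correction for larger groups.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import combinations
from typing import Iterable, Sequence, Tuple

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_MAX_N = 8


@lru_cache(maxsize=64)
def _exact_ranksum_pmf(n1: int, n2: int):
    """PMF of the rank sum of group 1 (sizes n1, n2, no ties).

    Returns (support, probabilities); computed by subset-sum counting.
    """
    n = n1 + n2
    # ways[k][s] = number of k-subsets of ranks 1..n with sum s
    max_sum = n * (n + 1) // 2
    ways = np.zeros((n1 + 1, max_sum + 1), dtype=np.int64)
    ways[0, 0] = 1
    for r in range(1, n + 1):
        for k in range(min(r, n1), 0, -1):
            ways[k, r:] += ways[k - 1, : max_sum + 1 - r]
    total = ways[n1].sum()
    support = np.nonzero(ways[n1])[0]
    return support, ways[n1][support] / total


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: str = "two-sided"
) -> Tuple[float, float]:
    """Wilcoxon rank-sum test of ``x`` vs ``y``.

    ``alternative='greater'`` tests whether ``x`` tends to exceed ``y``.
    Returns (rank sum of x with mid-ranks, p-value).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = len(x), len(y)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([x, y])
    ranks = sps.rankdata(combined)
    w = float(ranks[:n1].sum())
    has_ties = len(np.unique(combined)) < n1 + n2

    if max(n1, n2) <= EXACT_MAX_N:
        if not has_ties:
            support, pmf = _exact_ranksum_pmf(n1, n2)
            p_ge = float(pmf[support >= w - 1e-9].sum())
            p_le = float(pmf[support <= w + 1e-9].sum())
        else:
            # enumerate which positions belong to group 1
            sums = np.array(
                [ranks[list(idx)].sum() for idx in combinations(range(n1 + n2), n1)]
            )
            p_ge = float(np.mean(sums >= w - 1e-9))
            p_le = float(np.mean(sums <= w + 1e-9))
    else:
        mu = n1 * (n1 + n2 + 1) / 2.0
        _, counts = np.unique(combined, return_counts=True)
        n = n1 + n2
        tie_term = ((counts**3 - counts).sum()) / (n * (n - 1)) if n > 1 else 0.0
        var = n1 * n2 / 12.0 * (n + 1 - tie_term)
        if var <= 0:
            return w, 1.0
        sd = np.sqrt(var)
        # continuity-corrected tails
        p_ge = float(sps.norm.sf((w - mu - 0.5) / sd))
        p_le = float(sps.norm.cdf((w - mu + 0.5) / sd))

    if alternative == "greater":
        p = p_ge
    elif alternative == "less":
        p = p_le
    elif alternative == "two-sided":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError(f"unknown alternative {alternative!r}")
    return w, p


def binom_two_sided(k: int, n: int, p0: float) -> float:
    """Two-sided binomial p by tail doubling, capped at 1.

    Degenerate rates: when ``p0`` is 0 or 1 and the count matches the
    (certain) expectation the p-value is 1, otherwise 0.
    """
    if not (0 <= k <= n):
        raise ValueError("require 0 <= k <= n")
    if p0 <= 0.0:
        return 1.0 if k == 0 else 0.0
    if p0 >= 1.0:
        return 1.0 if k == n else 0.0
    lower = sps.binom.cdf(k, n, p0)
    upper = sps.binom.sf(k - 1, n, p0)
    return float(min(1.0, 2.0 * min(lower, upper)))


def adjust_pvalues(p: Iterable[float], method: str = "BH") -> np.ndarray:
    """Step-up FDR adjustment (BH) or its dependency-robust variant (BY)."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    key = {"BH": "fdr_bh", "BY": "fdr_by"}.get(method.upper())
    if key is None:
        raise ValueError(f"unknown adjustment method {method!r}")
    return multipletests(p, method=key)[1]
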