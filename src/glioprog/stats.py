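"""Exact small-sample statistics for cohort comparisons.

Implements the two tests used for the cohort-level claims: Fisher's exact
test on 2x2 contingency tables (two-sided by the null-probability /
"minlike" ordering) and the exact two-sided Wilcoxon rank-sum test.  Both
are written against enumerable definitions so they can be checked against
brute-force enumeration; for larger inputs the rank-sum test falls back to
the tie-corrected normal approximation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class RankSumResult:
    statistic: float  # rank-sum W of group a
    p_value: float
    exact: bool  # True when obtained by exhaustive enumeration


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher exact p-value for a 2x2 table ``[[a, b], [c, d]]``.

    Conditional on the margins, the table count ``a`` follows a
    hypergeometric distribution.  The two-sided p-value sums the
    probabilities of all tables whose null probability does not exceed the
    observed table's (the "minlike" ordering used by R's ``fisher.test``),
    with a small relative tolerance so ties in probability are included
    despite floating-point rounding.
    """
    arr = np.asarray(table, dtype=np.int64)
    if arr.shape != (2, 2) or (arr < 0).any():
        raise ValueError("table must be 2x2 with non-negative integer cells")
    a, b = arr[0]
    c, d = arr[1]
    n = a + b + c + d
    row1 = a + b
    col1 = a + c
    if n == 0 or row1 in (0, n) or col1 in (0, n):
        warnings.warn("degenerate margin: Fisher p defined as 1", stacklevel=2)
        return 1.0
    rv = sps.hypergeom(n, col1, row1)
    amin = max(0, row1 + col1 - n)
    amax = min(row1, col1)
    support = np.arange(amin, amax + 1)
    probs = rv.pmf(support)
    p_obs = rv.pmf(a)
    p = probs[probs <= p_obs * (1 + 1e-9)].sum()
    return float(min(p, 1.0))


def _rank_sum_counts(n_a: int, n_b: int) -> np.ndarray:
    """Number of ways to pick ``n_a`` of ranks 1..n_a+n_b with each rank sum.

    Classic subset-sum dynamic programme; index w of the returned vector is
    the count of n_a-subsets whose rank total equals w.
    """
    n = n_a + n_b
    max_w = n_a * n // 1 if n_a else 0
    max_w = sum(range(n - n_a + 1, n + 1))
    # table[k][w] -> count of k-subsets with sum w; rolled over k
    counts = np.zeros((n_a + 1, max_w + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for rank in range(1, n + 1):
        for k in range(min(rank, n_a), 0, -1):
            counts[k, rank:] += counts[k - 1, : max_w + 1 - rank]
    return counts[n_a]


def wilcoxon_rank_sum_exact(
    group_a, group_b, exact_limit: int = 20
) -> RankSumResult:
    """Two-sided Wilcoxon rank-sum test.

    Exact enumeration (over all C(n_a+n_b, n_a) rank assignments, via a
    rank-sum counting recursion) is used when the combined sample size is
    at most ``exact_limit`` and the data are tie-free; the p-value doubles
    the smaller tail of the rank-sum statistic, capped at 1.  Otherwise a
    tie-corrected normal approximation is used and flagged.
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be nonempty")
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    w = float(ranks[: a.size].sum())
    has_ties = np.unique(pooled).size < pooled.size
    if a.size + b.size <= exact_limit and not has_ties:
        counts = _rank_sum_counts(a.size, b.size)
        total = counts.sum()
        wi = int(round(w))
        lower = counts[: wi + 1].sum() / total
        upper = counts[wi:].sum() / total
        p = min(1.0, 2.0 * min(lower, upper))
        return RankSumResult(statistic=w, p_value=float(p), exact=True)
    # Normal approximation with tie correction on the rank-sum statistic.
    n_a, n_b = a.size, b.size
    n = n_a + n_b
    mu = n_a * (n + 1) / 2.0
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
    var = n_a * n_b / 12.0 * (n + 1 - tie_term)
    if var == 0:
        return RankSumResult(statistic=w, p_value=1.0, exact=False)
    z = (w - mu - math.copysign(0.5, w - mu)) / math.sqrt(var) if w != mu else 0.0
    p = min(1.0, 2.0 * sps.norm.sf(abs(z)))
    return RankSumResult(statistic=w, p_value=float(p), exact=False)
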