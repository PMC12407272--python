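"""Statistical primitives shared by all pipeline stages.

The test procedures (Benjamini-Hochberg step-up, two-sided Fisher exact by
the point-probability rule, exact and normal-approximation rank-sum tests,
upper-tail hypergeometric enrichment) are implemented here; underlying
distribution functions come from scipy.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln
from scipy.stats import hypergeom, norm

__all__ = [
    "TestResult",
    "bh_adjust",
    "fisher_exact",
    "fisher_exact_many",
    "rank_sum_test",
    "hypergeom_enrich",
    "t_test_welch",
    "root_activity",
]

#: relative tolerance when comparing table probabilities in the two-sided
#: Fisher rule (same role as the epsilon in R's fisher.test)
_REL_EPS = 1e-7


@dataclass(frozen=True)
class TestResult:
    """Generic test outcome; ``effect`` is context-defined (log2FC, odds
    ratio, fold enrichment or location shift)."""

    statistic: float
    p_value: float
    effect: float


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="mergesort")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adj, 1.0)
    return out


def _log_comb(n, k):
    return gammaln(n + 1) - gammaln(k + 1) - gammaln(n - k + 1)


def _hypergeom_pmf(k, N, K, n):
    """Vectorized hypergeometric pmf via log-gamma (fast for large margins)."""
    k, N, K, n = (np.asarray(x, dtype=np.float64) for x in (k, N, K, n))
    return np.exp(_log_comb(K, k) + _log_comb(N - K, n - k) - _log_comb(N, n))


def _odds_ratio(a: float, b: float, c: float, d: float) -> float:
    if b * c == 0:
        return math.inf if a * d > 0 else math.nan
    return (a * d) / (b * c)


def fisher_exact(a: int, b: int, c: int, d: int) -> TestResult:
    """Two-sided Fisher exact test on the 2x2 table [[a, b], [c, d]].

    The two-sided p sums the probabilities of all tables (same margins)
    whose point probability does not exceed that of the observed table.
    Effect is the sample odds ratio (infinite when b*c == 0).
    """
    for v in (a, b, c, d):
        if v < 0 or int(v) != v:
            raise ValueError("table entries must be nonnegative integers")
    if a + b + c + d == 0:
        raise ValueError("all-zero contingency table")
    N, K, n = a + b + c + d, a + b, a + c
    lo, hi = max(0, K - (N - n)), min(K, n)
    support = np.arange(lo, hi + 1)
    pmf = _hypergeom_pmf(support, N, K, n)
    p_obs = float(_hypergeom_pmf(a, N, K, n))
    p = float(pmf[pmf <= p_obs * (1 + _REL_EPS)].sum())
    return TestResult(statistic=float(a), p_value=min(p, 1.0),
                      effect=_odds_ratio(a, b, c, d))


def fisher_exact_many(a, b, c, d) -> np.ndarray:
    """Vectorized two-sided Fisher p-values for many 2x2 tables.

    Intended for window-level enrichment testing where the first row
    (a + b) is small while the column margins are large, so the
    hypergeometric support is short.  Returns an array of p-values.
    """
    a, b, c, d = (np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    N, K, n = a + b + c + d, a + b, a + c
    lo = np.maximum(0, K - (N - n))
    hi = np.minimum(K, n)
    width = int((hi - lo).max()) + 1 if a.size else 0
    ks = lo[:, None] + np.arange(width)[None, :]
    valid = ks <= hi[:, None]
    pmf = _hypergeom_pmf(np.where(valid, ks, lo[:, None]), N[:, None],
                         K[:, None], n[:, None])
    pmf = np.where(valid, pmf, 0.0)
    p_obs = _hypergeom_pmf(a, N, K, n)
    keep = pmf <= (p_obs * (1 + _REL_EPS))[:, None]
    return np.minimum((pmf * keep).sum(axis=1), 1.0)


def _rank_sum_pmf(n1: int, n2: int) -> np.ndarray:
    """Exact pmf of the rank sum of sample 1 (no ties), offset = min sum.

    DP over "number of subsets of size m from ranks 1..N with sum s".
    """
    N = n1 + n2
    max_sum = n1 * (2 * N - n1 + 1) // 2
    ways = np.zeros((n1 + 1, max_sum + 1))
    ways[0, 0] = 1.0
    for r in range(1, N + 1):
        m_hi = min(r, n1)
        for m in range(m_hi, 0, -1):
            ways[m, r:] += ways[m - 1, :-r] if r else ways[m - 1, :]
    total = ways[n1].sum()
    return ways[n1] / total


def _hodges_lehmann(x: np.ndarray, y: np.ndarray) -> float:
    if x.size * y.size <= 4_000_000:
        return float(np.median(x[:, None] - y[None, :]))
    return float(np.median(x) - np.median(y))


def rank_sum_test(x, y) -> TestResult:
    """Two-sided Mann-Whitney/Wilcoxon rank-sum test.

    Exact enumeration of the rank-sum distribution when both samples have
    at most 25 observations and there are no ties; otherwise the normal
    approximation with tie and continuity correction.  Effect is the
    Hodges-Lehmann location shift of x relative to y.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    n1, n2 = x.size, y.size
    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(statistic=n1 * (n1 + n2 + 1) / 2.0, p_value=1.0, effect=0.0)
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(pooled.size)
    sorted_vals = pooled[order]
    # midranks for ties
    i = 0
    while i < pooled.size:
        j = i
        while j + 1 < pooled.size and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    w = float(ranks[:n1].sum())
    has_ties = np.unique(pooled).size < pooled.size
    effect = _hodges_lehmann(x, y)
    if not has_ties and n1 <= 25 and n2 <= 25:
        pmf = _rank_sum_pmf(n1, n2)  # indexed by absolute rank sum
        idx = int(round(w))
        lower = float(pmf[: idx + 1].sum())
        upper = float(pmf[idx:].sum())
        p = min(1.0, 2.0 * min(lower, upper))
        return TestResult(statistic=w, p_value=p, effect=effect)
    # normal approximation with tie correction and continuity correction
    N = n1 + n2
    mu = n1 * (N + 1) / 2.0
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = float(((counts**3 - counts).sum())) / (N * (N - 1))
    var = n1 * n2 / 12.0 * ((N + 1) - tie_term)
    if var <= 0:
        return TestResult(statistic=w, p_value=1.0, effect=effect)
    z = (abs(w - mu) - 0.5) / math.sqrt(var)
    p = min(1.0, 2.0 * float(norm.sf(max(z, 0.0))))
    return TestResult(statistic=w, p_value=p, effect=effect)


def hypergeom_enrich(hits_in_set: int, set_size: int, hits_total: int,
                     universe: int) -> TestResult:
    """Upper-tail hypergeometric enrichment of a gene set.

    p = P[X >= hits_in_set], X ~ Hypergeom(universe, hits_total, set_size);
    effect is the fold enrichment (hits_in_set/set_size)/(hits_total/universe).
    """
    if universe == 0:
        raise ValueError("universe must be positive")
    if hits_in_set > min(set_size, hits_total):
        raise ValueError("hits_in_set exceeds set_size or hits_total")
    if max(set_size, hits_total) > universe:
        raise ValueError("set sizes exceed universe")
    p = float(hypergeom.sf(hits_in_set - 1, universe, hits_total, set_size))
    expected = hits_total / universe * set_size
    effect = (hits_in_set / set_size) / (hits_total / universe) if expected > 0 else math.nan
    return TestResult(statistic=float(hits_in_set), p_value=min(p, 1.0), effect=effect)


def t_test_welch(x, y) -> TestResult:
    """Two-tailed Welch two-sample t-test; effect is the mean difference."""
    from scipy.stats import ttest_ind

    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    res = ttest_ind(x, y, equal_var=False)
    return TestResult(statistic=float(res.statistic), p_value=float(res.pvalue),
                      effect=float(x.mean() - y.mean()))


def root_activity(ttc_reduction_mg: float, fresh_weight_g: float, hours: float,
                  literal: bool = False) -> float:
    """Root dehydrogenase activity from the TTC reduction assay.

    Conventional reading (default): mg TTC reduced per gram fresh root per
    hour, ttc / (weight * hours).  ``literal=True`` selects the alternative
    ttc / (weight / hours) reading, which has units mg*h/g.
    """
    if fresh_weight_g <= 0 or hours <= 0:
        raise ValueError("fresh weight and time must be positive")
    if ttc_reduction_mg < 0:
        raise ValueError("TTC reduction cannot be negative")
    if literal:
        return ttc_reduction_mg / (fresh_weight_g / hours)
    return ttc_reduction_mg / (fresh_weight_g * hours)
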