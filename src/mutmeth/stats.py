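"""Statistical kernel shared by every analysis stage.

Rank-based two-group tests with an explicit direction convention, BH
q-values, rank/product-moment correlation, and the hypergeometric
enrichment tail.  The direction of every two-group comparison is the sign
of ``median(x) - median(y)``: positive means the first (mutated) group
sits higher on the tested variable.
"""

from __future__ import annotations

from dataclasses import dataclass
from math import comb
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

Alternative = Literal["two_sided", "greater", "less"]

_SCIPY_ALT = {"two_sided": "two-sided", "greater": "greater", "less": "less"}

#: pooled size at or below which the rank-sum null is enumerated exactly
EXACT_ENUMERATION_LIMIT = 20


@dataclass(frozen=True)
class TestResult:
    """Outcome of a two-group rank-sum comparison.

    ``direction`` is the sign of the median difference (group1 - group2);
    ``effect`` is that median difference in the units of the tested
    variable.
    """

    p_value: float
    direction: int
    effect: float
    n1: int
    n2: int


def _doubled_midranks(pooled: np.ndarray) -> np.ndarray:
    """Midranks of the pooled sample, doubled so ties stay integral."""
    ranks = sps.rankdata(pooled, method="average")
    doubled = np.rint(ranks * 2).astype(np.int64)
    return doubled


def _exact_rank_sum_distribution(doubled_ranks: np.ndarray, n1: int) -> np.ndarray:
    """Exact null distribution of the (doubled) rank sum of group 1.

    Counts, for every achievable doubled rank sum ``s``, the number of
    ways to draw ``n1`` of the pooled ranks summing to ``s``.  Dynamic
    programme over items; ties enter through repeated midranks.
    """
    max_sum = int(doubled_ranks.sum())
    # counts[k, s] = number of k-subsets with doubled rank sum s
    counts = np.zeros((n1 + 1, max_sum + 1), dtype=np.float64)
    counts[0, 0] = 1.0
    for r in doubled_ranks:
        # iterate k downwards so each item is used at most once
        for k in range(n1, 0, -1):
            counts[k, r:] += counts[k - 1, : max_sum + 1 - r]
    return counts[n1]


def _exact_rank_sum_p(
    doubled_ranks: np.ndarray, n1: int, w_doubled: int, alternative: Alternative
) -> float:
    dist = _exact_rank_sum_distribution(doubled_ranks, n1)
    total = comb(len(doubled_ranks), n1)
    sums = np.arange(dist.size)
    p_le = dist[sums <= w_doubled].sum() / total
    p_ge = dist[sums >= w_doubled].sum() / total
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum_test(
    x: Sequence[float], y: Sequence[float], alternative: Alternative = "two_sided"
) -> TestResult:
    """Wilcoxon rank-sum (Mann-Whitney) test of two independent groups.

    For pooled sizes up to :data:`EXACT_ENUMERATION_LIMIT` the null
    distribution of the rank sum is enumerated exactly over all
    ``C(n1+n2, n1)`` group assignments, with midranks under ties; larger
    samples use the normal approximation with tie and continuity
    corrections.
    """
    if alternative not in _SCIPY_ALT:
        raise ValueError(f"unknown alternative: {alternative!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("rank_sum_test requires finite values")

    effect = float(np.median(x) - np.median(y))
    direction = int(np.sign(effect))
    n1, n2 = x.size, y.size

    pooled = np.concatenate([x, y])
    if np.all(pooled == pooled[0]):
        return TestResult(1.0, 0, 0.0, n1, n2)

    if n1 + n2 <= EXACT_ENUMERATION_LIMIT:
        doubled = _doubled_midranks(pooled)
        w_doubled = int(doubled[:n1].sum())
        p = _exact_rank_sum_p(doubled, n1, w_doubled, alternative)
    else:
        res = sps.mannwhitneyu(
            x, y, alternative=_SCIPY_ALT[alternative], method="asymptotic",
            use_continuity=True,
        )
        p = float(res.pvalue)
    return TestResult(min(p, 1.0), direction, effect, n1, n2)


def rank_sum_matrix(
    x: np.ndarray, y: np.ndarray, alternative: Alternative = "two_sided"
) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise rank-sum test for many features at once.

    ``x`` and ``y`` are features-by-samples arrays holding the two groups'
    columns; missing values (NaN) are omitted per row.  Returns the
    per-row p-value (normal approximation, tie/continuity corrected) and
    the per-row median difference ``median(x) - median(y)``.  Rows that
    are constant across both groups get p = 1.
    """
    x = np.atleast_2d(np.asarray(x, dtype=float))
    y = np.atleast_2d(np.asarray(y, dtype=float))
    if x.shape[0] != y.shape[0]:
        raise ValueError("x and y must have the same number of rows")
    if x.shape[1] + y.shape[1] <= EXACT_ENUMERATION_LIMIT:
        # small pooled size: defer to the exact-enumeration kernel per row
        p = np.empty(x.shape[0])
        med_diff = np.empty(x.shape[0])
        for i in range(x.shape[0]):
            xi = x[i][np.isfinite(x[i])]
            yi = y[i][np.isfinite(y[i])]
            res = rank_sum_test(xi, yi, alternative)
            p[i] = res.p_value
            med_diff[i] = res.effect
        return p, med_diff
    with np.errstate(invalid="ignore", divide="ignore"):
        res = sps.mannwhitneyu(
            x, y, alternative=_SCIPY_ALT[alternative], method="asymptotic",
            use_continuity=True, axis=1, nan_policy="omit",
        )
        p = np.asarray(res.pvalue, dtype=float)
    # constant rows yield 0/0 -> NaN; no evidence either way
    p = np.where(np.isnan(p), 1.0, np.minimum(p, 1.0))
    med_diff = np.nanmedian(x, axis=1) - np.nanmedian(y, axis=1)
    return p, med_diff


def bh_qvalues(p: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    ``q_(i) = min_{j >= i} p_(j) * m / j`` on the sorted p-values, capped
    at 1 and mapped back to the original positions.
    """
    p = np.asarray(list(p) if not isinstance(p, np.ndarray) else p, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def spearman_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Spearman rank correlation with a t-approximation p-value.

    Pairs with a missing member are dropped; at least three complete
    pairs are required, and either vector being constant after the rank
    transform is an error (the correlation is undefined).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("need at least 3 complete pairs")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a constant vector")
    rho, p = sps.spearmanr(x, y)
    return float(rho), float(p)


def pearson_correlation(
    x: Sequence[float], y: Sequence[float]
) -> tuple[float, float]:
    """Product-moment correlation; p from the t distribution on n-2 df."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("pearson_correlation requires finite values")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("correlation undefined for a zero-variance vector")
    r, p = sps.pearsonr(x, y)
    return float(r), float(p)


def hypergeometric_enrichment(
    hits: int, draw_size: int, set_size: int, universe_size: int
) -> float:
    """Upper-tail hypergeometric probability ``P(X >= hits)``.

    ``draw_size`` genes are drawn from a universe of ``universe_size`` of
    which ``set_size`` belong to the set; ``hits`` is the observed
    overlap.
    """
    if not (0 <= hits <= min(draw_size, set_size)):
        raise ValueError("hits must lie in [0, min(draw_size, set_size)]")
    if max(draw_size, set_size) > universe_size:
        raise ValueError("draw and set sizes cannot exceed the universe")
    return float(sps.hypergeom.sf(hits - 1, universe_size, set_size, draw_size))
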