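"""Statistical kernel vs independent brute-force oracles."""

from __future__ import annotations

import itertools
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from mutmeth.stats import (
    bh_qvalues,
    hypergeometric_enrichment,
    pearson_correlation,
    rank_sum_test,
    spearman_correlation,
)


def brute_force_rank_sum_p(x, y, alternative="two_sided"):
    """Oracle: enumerate every assignment of pooled values to group 1
    via itertools (independent of the DP implementation)."""
    pooled = np.concatenate([x, y])
    ranks = sps.rankdata(pooled)
    n1 = len(x)
    w_obs = ranks[:n1].sum()
    sums = [sum(ranks[list(c)])
            for c in itertools.combinations(range(len(pooled)), n1)]
    sums = np.array(sums)
    p_le = np.mean(sums <= w_obs + 1e-9)
    p_ge = np.mean(sums >= w_obs - 1e-9)
    if alternative == "greater":
        return min(1.0, p_ge)
    if alternative == "less":
        return min(1.0, p_le)
    return min(1.0, 2 * min(p_le, p_ge))


def brute_force_bh(p):
    """Oracle: sort, step-up minima, remap — plain Python."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q_sorted = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * m / rank)
        q_sorted[rank - 1] = running
    q = [0.0] * m
    for rank, i in enumerate(order):
        q[i] = q_sorted[rank]
    return np.array(q)


class TestRankSum:
    def test_identical_groups_p_one(self):
        res = rank_sum_test([1, 2, 3], [1, 2, 3])
        assert res.p_value == 1.0 and res.direction == 0

    def test_hand_enumerated_two_sided(self):
        # C(5,2)=10 assignments; P(W<=3)=1/10, doubled
        res = rank_sum_test([1, 2], [3, 4, 5])
        assert res.p_value == pytest.approx(0.2)
        assert res.direction == -1

    def test_one_sided_with_ties(self):
        res = rank_sum_test([9, 9], [1, 1, 1], "greater")
        assert res.p_value == pytest.approx(
            brute_force_rank_sum_p([9, 9], [1, 1, 1], "greater"))
        assert res.direction == 1

    @pytest.mark.parametrize("alternative", ["two_sided", "greater", "less"])
    def test_exact_branch_matches_enumeration_oracle(self, alternative):
        rng = np.random.default_rng(0)
        for _ in range(80):
            n1 = int(rng.integers(1, 7))
            n2 = int(rng.integers(1, 8 - n1 + 1)) if n1 < 7 else 1
            # mix tie-free and tied draws
            vals = rng.choice([rng.normal(size=n1 + n2),
                               rng.integers(0, 4, n1 + n2).astype(float)])
            x, y = vals[:n1], vals[n1:]
            got = rank_sum_test(x, y, alternative).p_value
            want = brute_force_rank_sum_p(x, y, alternative)
            assert got == pytest.approx(want, abs=1e-12)

    def test_symmetry_two_sided(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=6)
            y = rng.normal(size=5)
            a = rank_sum_test(x, y)
            b = rank_sum_test(y, x)
            assert a.p_value == pytest.approx(b.p_value)
            assert a.direction == -b.direction

    def test_exact_close_to_normal_approximation(self):
        # spot-check |delta p| <= 0.02 at n1=n2=10, tie-free
        rng = np.random.default_rng(2)
        for _ in range(10):
            x = rng.normal(size=10)
            y = rng.normal(size=10)
            exact = rank_sum_test(x, y).p_value
            approx = sps.mannwhitneyu(x, y, alternative="two-sided",
                                      method="asymptotic").pvalue
            assert abs(exact - approx) <= 0.02

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            rank_sum_test([], [1.0])


class TestBH:
    def test_hand_computed_step_up(self):
        q = bh_qvalues([0.01, 0.02, 0.03, 0.04])
        assert q == pytest.approx([0.04, 0.04, 0.04, 0.04])

    def test_singleton_identity(self):
        assert bh_qvalues([0.5]) == pytest.approx([0.5])

    def test_all_ones(self):
        assert bh_qvalues([1, 1, 1]) == pytest.approx([1, 1, 1])

    def test_matches_independent_oracle_on_random_vectors(self):
        rng = np.random.default_rng(3)
        for _ in range(200):
            p = rng.uniform(size=int(rng.integers(1, 40)))
            assert bh_qvalues(p) == pytest.approx(brute_force_bh(p))

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_qvalues([0.5, 1.2])

    @settings(deadline=None, derandomize=True, max_examples=50)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_q_dominates_p_and_bonferroni_subset(self, p):
        p = np.array(p)
        q = bh_qvalues(p)
        assert np.all(q >= p - 1e-12)
        assert np.all(q <= 1 + 1e-12)
        alpha = 0.05
        bonf = p < alpha / len(p)
        bh = q < alpha
        assert np.all(bh[bonf])  # BH rejections contain Bonferroni's


class TestCorrelations:
    def test_spearman_monotone_extremes(self):
        assert spearman_correlation([1, 2, 3], [10, 20, 30])[0] == \
            pytest.approx(1.0)
        assert spearman_correlation([1, 2, 3], [3, 2, 1])[0] == \
            pytest.approx(-1.0)

    def test_spearman_with_tie_hand_value(self):
        # Pearson of midranks (1,2,3) vs (1.5,1.5,3) = sqrt(3)/2
        rho, _ = spearman_correlation([1, 2, 3], [2, 2, 3])
        assert rho == pytest.approx(np.sqrt(3) / 2)

    def test_spearman_monotone_transform_invariance(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=20)
        y = rng.normal(size=20)
        rho1, p1 = spearman_correlation(x, y)
        rho2, p2 = spearman_correlation(np.exp(x), y ** 3 + 5 * y)
        assert rho1 == pytest.approx(rho2)
        assert p1 == pytest.approx(p2)

    def test_spearman_constant_errors(self):
        with pytest.raises(ValueError):
            spearman_correlation([1, 1, 1], [1, 2, 3])

    def test_pearson_linear_and_hand_value(self):
        x = np.array([1.0, 2, 3])
        assert pearson_correlation(x, 2 * x + 1)[0] == pytest.approx(1.0)
        r, _ = pearson_correlation([1, 2, 3], [1, 2, 4])
        assert r == pytest.approx(3 / np.sqrt(2 * 14 / 3))

    def test_pearson_orthogonal_deviations(self):
        r, _ = pearson_correlation([1, 2, 3], [1, -2, 1])
        assert r == pytest.approx(0.0, abs=1e-12)

    def test_pearson_zero_variance_errors(self):
        with pytest.raises(ValueError):
            pearson_correlation([2, 2, 2], [1, 2, 3])


class TestHypergeometric:
    def test_zero_hits_is_one(self):
        assert hypergeometric_enrichment(0, 4, 5, 10) == pytest.approx(1.0)

    def test_hand_computed_tail(self):
        # C(5,4)C(5,0)/C(10,4) = 5/210
        assert hypergeometric_enrichment(4, 4, 5, 10) == \
            pytest.approx(5 / 210)

    def test_set_equals_universe_degenerate(self):
        assert hypergeometric_enrichment(4, 4, 10, 10) == pytest.approx(1.0)

    def test_matches_exhaustive_enumeration(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            universe = int(rng.integers(4, 13))
            set_size = int(rng.integers(1, universe + 1))
            draw = int(rng.integers(1, universe + 1))
            hits = int(rng.integers(0, min(draw, set_size) + 1))
            members = set(range(set_size))
            total = hit_count = 0
            for combo in itertools.combinations(range(universe), draw):
                total += 1
                if len(members & set(combo)) >= hits:
                    hit_count += 1
            want = hit_count / total
            got = hypergeometric_enrichment(hits, draw, set_size, universe)
            assert got == pytest.approx(want, abs=1e-12)

    def test_inconsistent_counts_error(self):
        with pytest.raises(ValueError):
            hypergeometric_enrichment(5, 4, 5, 10)
        with pytest.raises(ValueError):
            hypergeometric_enrichment(1, 4, 11, 10)
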