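import math
from fractions import Fraction
from itertools import combinations, product

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cd8mir.io_core import Cd8mirError, ValidationError
from cd8mir.stats_tests import (
    ContingencyTable2x2,
    fisher_exact,
    log_or_ci,
    mann_whitney_u,
    odds_ratio,
    wilcoxon_signed_rank,
)

# ---------------------------------------------------------------------------
# independent brute-force oracles (kept deliberately naive)
# ---------------------------------------------------------------------------


def brute_mann_whitney_p(x, y):
    """Enumerate all group labelings; U counted pairwise; doubled smaller tail."""
    pooled = list(x) + list(y)
    nx = len(x)

    def u_stat(idx):
        xs = [pooled[i] for i in idx]
        ys = [pooled[i] for i in range(len(pooled)) if i not in set(idx)]
        return sum(1 for a in xs for b in ys if a > b)

    u_obs = sum(1 for a in x for b in y if a > b)
    us = [u_stat(idx) for idx in combinations(range(len(pooled)), nx)]
    total = len(us)
    lower = sum(1 for u in us if u <= u_obs)
    upper = sum(1 for u in us if u >= u_obs)
    return min(1, Fraction(2 * min(lower, upper), total))


def brute_wilcoxon_p(diffs):
    """Enumerate all sign assignments of the rank magnitudes."""
    d = [v for v in diffs if v != 0]
    n = len(d)
    order = sorted(range(n), key=lambda i: abs(d[i]))
    ranks = [0] * n
    for r, i in enumerate(order, start=1):
        ranks[i] = r
    w_obs = sum(r for r, v in zip(ranks, d) if v > 0)
    ws = []
    for signs in product([0, 1], repeat=n):
        ws.append(sum(r for r, s in zip(ranks, signs) if s))
    total = len(ws)
    lower = sum(1 for w in ws if w <= w_obs)
    upper = sum(1 for w in ws if w >= w_obs)
    return min(1, Fraction(2 * min(lower, upper), total))


def brute_fisher_p(a, b, c, d):
    """Exact rational hypergeometric enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = a + b + c + d
    denom = math.comb(n, c1)

    def prob(k):
        return Fraction(math.comb(r1, k) * math.comb(r2, c1 - k), denom)

    p_obs = prob(a)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        if prob(k) <= p_obs:
            total += prob(k)
    return total


# ---------------------------------------------------------------------------


class TestOddsRatio:
    def test_printed_values_exact(self):
        assert odds_ratio(ContingencyTable2x2(9, 4, 5, 11)) == Fraction(99, 20)
        assert odds_ratio(ContingencyTable2x2(7, 4, 5, 8)) == Fraction(56, 20)

    @pytest.mark.parametrize("k", [1, 3, 9])
    def test_symmetric_counts_give_one(self, k):
        assert odds_ratio(ContingencyTable2x2(k, k, k, k)) == 1.0

    def test_zero_denominator(self):
        with pytest.raises(Cd8mirError):
            odds_ratio(ContingencyTable2x2(3, 0, 2, 5))
        assert odds_ratio(ContingencyTable2x2(3, 0, 2, 5), haldane=True) == pytest.approx(
            (3.5 * 5.5) / (0.5 * 2.5)
        )

    def test_negative_counts_rejected(self):
        with pytest.raises(ValidationError):
            ContingencyTable2x2(-1, 0, 0, 1)

    def test_woolf_ci_brackets_or(self):
        t = ContingencyTable2x2(9, 4, 5, 11)
        lo, hi = log_or_ci(t)
        assert lo < odds_ratio(t) < hi


class TestFisher:
    def test_phenotype_table(self):
        res = fisher_exact(ContingencyTable2x2(9, 4, 5, 11))
        assert res.exact
        assert res.p_two_sided == pytest.approx(0.06559547883437, abs=1e-10)

    def test_uniform_table(self):
        assert fisher_exact(ContingencyTable2x2(1, 1, 1, 1)).p_two_sided == pytest.approx(1.0)

    def test_nicotine_cohort_table(self):
        res = fisher_exact(ContingencyTable2x2(7, 4, 5, 8))
        assert res.p_two_sided == pytest.approx(float(brute_fisher_p(7, 4, 5, 8)), abs=1e-10)
        assert round(res.p_two_sided, 2) == 0.41

    @given(
        a=st.integers(0, 8), b=st.integers(0, 8), c=st.integers(0, 8), d=st.integers(0, 8)
    )
    @settings(max_examples=150, deadline=None)
    def test_matches_rational_enumeration(self, a, b, c, d):
        if min(a + b, c + d, a + c, b + d) == 0 or a + b + c + d == 0:
            return
        res = fisher_exact(ContingencyTable2x2(a, b, c, d))
        assert res.p_two_sided == pytest.approx(float(brute_fisher_p(a, b, c, d)), abs=1e-9)

    @given(a=st.integers(1, 6), b=st.integers(1, 6), c=st.integers(1, 6), d=st.integers(1, 6))
    @settings(max_examples=60, deadline=None)
    def test_transpose_and_swap_symmetry(self, a, b, c, d):
        p = fisher_exact(ContingencyTable2x2(a, b, c, d)).p_two_sided
        assert fisher_exact(ContingencyTable2x2(a, c, b, d)).p_two_sided == pytest.approx(p)
        assert fisher_exact(ContingencyTable2x2(c, d, a, b)).p_two_sided == pytest.approx(p)
        assert fisher_exact(ContingencyTable2x2(b, a, d, c)).p_two_sided == pytest.approx(p)


class TestMannWhitney:
    def test_extreme_ordering_3v3(self):
        res = mann_whitney_u([10, 11, 12], [1, 2, 3])
        assert res.exact
        assert res.p_two_sided == pytest.approx(2 / 20)

    def test_identical_multisets_approx_path(self):
        res = mann_whitney_u([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert not res.exact
        assert res.p_two_sided == pytest.approx(1.0)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValidationError):
            mann_whitney_u([], [1.0])

    def test_5v5_enumeration_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            x = rng.normal(0, 1, 5)
            y = rng.normal(0.5, 1, 5)
            res = mann_whitney_u(x, y)
            assert res.exact and res.method == "exact-enumeration"
            assert res.p_two_sided == pytest.approx(float(brute_mann_whitney_p(x, y)), abs=1e-12)

    def test_large_n_takes_approx_path(self):
        rng = np.random.default_rng(22)
        res = mann_whitney_u(rng.normal(0, 1, 20), rng.normal(0, 1, 20))
        assert res.method == "normal-approx"
        assert 0 <= res.p_two_sided <= 1

    @given(
        x=st.lists(st.integers(0, 1000), min_size=2, max_size=4),
        y=st.lists(st.integers(0, 1000), min_size=2, max_size=4),
    )
    @settings(max_examples=80, deadline=None)
    def test_monotone_transform_invariance(self, x, y):
        pooled = x + y
        if len(set(pooled)) < len(pooled):
            return
        p1 = mann_whitney_u(x, y).p_two_sided
        fx = [math.exp(v / 100.0) for v in x]
        fy = [math.exp(v / 100.0) for v in y]
        assert mann_whitney_u(fx, fy).p_two_sided == pytest.approx(p1, abs=1e-12)


class TestWilcoxon:
    def test_n8_uniform_signs(self):
        res = wilcoxon_signed_rank([-1, -2, -3, -4, -5, -6, -7, -8])
        assert res.exact
        assert res.p_two_sided == pytest.approx(2 / 256)

    def test_n6_uniform_signs(self):
        res = wilcoxon_signed_rank([1, 2, 3, 4, 5, 6])
        assert res.p_two_sided == pytest.approx(2 / 64)

    def test_single_nonzero_diff(self):
        assert wilcoxon_signed_rank([3.0]).p_two_sided == pytest.approx(1.0)

    def test_all_zero_diffs(self):
        res = wilcoxon_signed_rank([0.0, 0.0])
        assert res.p_two_sided == 1.0
        assert res.statistic == 0.0
        assert res.method == "all-zero"

    def test_zeros_dropped_reduce_n(self):
        res = wilcoxon_signed_rank([0.0, -1.0, -2.0, 0.0, -3.0])
        assert res.n == (3,)
        assert res.p_two_sided == pytest.approx(2 / 8)

    def test_tied_magnitudes_take_approx_path(self):
        res = wilcoxon_signed_rank([1.0, 1.0, -2.0, 3.0, 4.0, -5.0])
        assert res.method == "normal-approx"

    def test_enumeration_oracle(self):
        rng = np.random.default_rng(23)
        for _ in range(20):
            d = rng.normal(0.3, 1, 7)
            res = wilcoxon_signed_rank(d)
            assert res.exact
            assert res.p_two_sided == pytest.approx(float(brute_wilcoxon_p(d)), abs=1e-12)

    @given(d=st.lists(st.integers(-50, 50).filter(lambda v: v != 0), min_size=1, max_size=6))
    @settings(max_examples=80, deadline=None)
    def test_property_matches_brute_force(self, d):
        if len({abs(v) for v in d}) < len(d):
            return
        res = wilcoxon_signed_rank(d)
        assert res.p_two_sided == pytest.approx(float(brute_wilcoxon_p(d)), abs=1e-12)
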