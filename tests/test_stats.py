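"""Unit and property tests for the statistical kernels."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from agedmr.errors import DegenerateInputError
from agedmr.stats import (
    CorrelationResult,
    TwoByTwo,
    bh_adjust,
    fisher_exact_two_tailed,
    hypergeom_upper_tail,
    pearson,
    spearman,
    student_t_test,
)


def spearman_permutation_oracle(x, y):
    """Exact two-sided Spearman p by brute enumeration, via scipy's rho."""
    rho_obs = sps.spearmanr(x, y).statistic
    hits = total = 0
    for perm in itertools.permutations(y):
        r = sps.spearmanr(x, perm).statistic
        total += 1
        hits += abs(r) >= abs(rho_obs) - 1e-12
    return rho_obs, hits / total


class TestSpearman:
    def test_monotone_identity(self):
        res = spearman([1, 2, 3, 4, 5], [2, 4, 6, 8, 10])
        assert res.estimate == 1.0
        assert res.n_used == 5

    def test_reversal(self):
        assert spearman([1, 2, 3, 4, 5], [5, 4, 3, 2, 1]).estimate == -1.0

    @pytest.mark.parametrize(
        "y", [(1, 3, 2, 4, 6, 5), (6, 1, 4, 2, 5, 3), (1, 2, 2, 4, 3, 5)]
    )
    def test_exact_p_matches_permutation_enumeration(self, y):
        x = (1, 2, 3, 4, 5, 6)
        res = spearman(x, y)
        rho_ref, p_ref = spearman_permutation_oracle(x, y)
        assert res.estimate == pytest.approx(rho_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-12)

    def test_constant_vector_is_degenerate(self):
        with pytest.raises(DegenerateInputError):
            spearman([1, 2, 3, 4], [5, 5, 5, 5])

    def test_listwise_missing_removal(self):
        res = spearman([1, 2, 3, 4, np.nan], [2, 4, 6, 8, 0])
        assert res.n_used == 4
        assert res.estimate == 1.0

    @given(
        st.lists(st.floats(-100, 100), min_size=5, max_size=7),
        st.randoms(use_true_random=False),
    )
    @settings(max_examples=25, deadline=None)
    def test_symmetry(self, x, rnd):
        y = list(x)
        rnd.shuffle(y)
        if len(set(x)) < 2 or len(set(y)) < 2:
            return
        a = spearman(x, y)
        b = spearman(y, x)
        assert a.estimate == pytest.approx(b.estimate, abs=1e-12)
        assert a.p_value == pytest.approx(b.p_value, abs=1e-12)

    def test_null_calibration_at_study_n(self):
        """Type-I rate of the t-approximation at n=22 stays near nominal 0.05."""
        rng = np.random.default_rng(2024)
        n_reps, n = 10_000, 22
        hits = sum(
            spearman(rng.normal(size=n), rng.normal(size=n)).p_value < 0.05
            for _ in range(n_reps)
        )
        rate = hits / n_reps
        se = math.sqrt(0.05 * 0.95 / n_reps)
        assert abs(rate - 0.05) < 3 * se


class TestPearson:
    def test_affine_function(self):
        x = np.arange(6.0)
        assert pearson(x, 2 * x + 1).estimate == pytest.approx(1.0)

    def test_orthogonal(self):
        # zero covariance by construction
        res = pearson([1, -1, 1, -1], [1, 1, -1, -1])
        assert res.estimate == pytest.approx(0.0, abs=1e-15)

    def test_matches_covariance_formula(self):
        rng = np.random.default_rng(7)
        x, y = rng.normal(size=8), rng.normal(size=8)
        r_ref = float(
            ((x - x.mean()) * (y - y.mean())).sum()
            / math.sqrt(((x - x.mean()) ** 2).sum() * ((y - y.mean()) ** 2).sum())
        )
        assert pearson(x, y).estimate == pytest.approx(r_ref, abs=1e-12)

    @given(
        st.floats(0.1, 10), st.floats(-5, 5),
        st.integers(0, 2**31 - 1),
    )
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_positive_affine_transform(self, a, b, seed):
        rng = np.random.default_rng(seed)
        x, y = rng.normal(size=10), rng.normal(size=10)
        r0 = pearson(x, y)
        r1 = pearson(a * x + b, y)
        assert r0.estimate == pytest.approx(r1.estimate, abs=1e-9)
        assert r0.p_value == pytest.approx(r1.p_value, abs=1e-9)


class TestStudentT:
    def test_identical_groups(self):
        assert student_t_test([1, 2, 3], [1, 2, 3]) == 1.0

    def test_zero_variance_unequal_means(self):
        assert student_t_test([0, 0, 0, 0], [1, 1, 1, 1]) == 0.0

    def test_zero_variance_equal_means(self):
        assert student_t_test([2, 2], [2, 2]) == 1.0

    def test_matches_pooled_t_closed_form(self):
        g1, g2 = [1.1, 2.0, 2.9], [3.1, 4.0, 4.9]
        # pooled: means 2 and 4, ss = 2*1.62, df = 4, sp2 = 0.81
        t_ref = (2.0 - 4.0) / math.sqrt(0.81 * (1 / 3 + 1 / 3))
        p_ref = 2 * sps.t.sf(abs(t_ref), df=4)
        assert student_t_test(g1, g2) == pytest.approx(p_ref, rel=1e-12)

    def test_matches_scipy_equal_var(self):
        rng = np.random.default_rng(11)
        g1, g2 = rng.normal(size=9), rng.normal(0.4, 1.0, size=12)
        ref = sps.ttest_ind(g1, g2, equal_var=True).pvalue
        assert student_t_test(g1, g2) == pytest.approx(ref, rel=1e-12)


class TestFisherExact:
    def test_symmetric_table(self):
        assert fisher_exact_two_tailed([[1, 1], [1, 1]]) == 1.0

    def test_perfect_separation(self):
        assert fisher_exact_two_tailed([[5, 0], [0, 5]]) == pytest.approx(2 / 252)

    def test_zero_margin(self):
        assert fisher_exact_two_tailed([[0, 0], [3, 4]]) == 1.0

    def test_paper_scale_table(self):
        p = fisher_exact_two_tailed([[25, 61], [7, 79]])
        assert float(f"{p:.1g}") == 0.0007

    @given(st.integers(0, 12), st.integers(0, 12), st.integers(0, 12), st.integers(0, 12))
    @settings(max_examples=150, deadline=None)
    def test_matches_scipy_and_row_swap_invariant(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        p = fisher_exact_two_tailed([[a, b], [c, d]])
        assert 0 <= p <= 1
        assert p == pytest.approx(
            min(1.0, sps.fisher_exact([[a, b], [c, d]])[1]), abs=1e-12
        )
        assert p == pytest.approx(fisher_exact_two_tailed([[c, d], [a, b]]), abs=1e-15)

    def test_rejects_negative_counts(self):
        with pytest.raises(ValueError):
            TwoByTwo(-1, 2, 3, 4)


class TestHypergeomUpperTail:
    def test_zero_overlap_is_certain(self):
        assert hypergeom_upper_tail(0, 5, 5, 100) == 1.0

    def test_full_overlap_small_universe(self):
        # both 5-sets drawn from 10: identical sets have probability 1/C(10,5)
        assert hypergeom_upper_tail(5, 5, 5, 10) == pytest.approx(1 / 252)

    def test_enumeration_oracle(self):
        # P(X >= 2), X ~ Hypergeom(N=8, K=4, n=3), by direct counting
        ref = sum(
            math.comb(4, k) * math.comb(4, 3 - k) for k in (2, 3)
        ) / math.comb(8, 3)
        assert hypergeom_upper_tail(2, 4, 3, 8) == pytest.approx(ref, rel=1e-12)

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError):
            hypergeom_upper_tail(6, 5, 5, 10)
        with pytest.raises(ValueError):
            hypergeom_upper_tail(1, 11, 5, 10)


def test_bh_adjust_monotone_and_bounded():
    p = np.array([0.001, 0.02, 0.04, 0.5, 0.9])
    q = bh_adjust(p)
    assert (q >= p - 1e-15).all() and (q <= 1).all()
    assert (np.diff(q[np.argsort(p)]) >= -1e-15).all()
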