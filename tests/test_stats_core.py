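import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import chi2

from causal_gwas import (
    bh_fdr,
    g2_test,
    hwe_test,
    hypergeom_enrichment,
    ld_r2,
    maf,
    max_conditioning_size,
)
from causal_gwas.stats_core import hwe_statistic

from conftest import counts_to_column


def g2_brute(table):
    """Independent brute-force likelihood-ratio statistic on a 2-D table."""
    table = np.asarray(table, dtype=float)
    tot = table.sum()
    rows = table.sum(axis=1)
    cols = table.sum(axis=0)
    g = 0.0
    for i in range(table.shape[0]):
        for j in range(table.shape[1]):
            o = table[i, j]
            if o > 0:
                g += 2.0 * o * math.log(o / (rows[i] * cols[j] / tot))
    return g


def table_to_columns(table):
    y, x = [], []
    for i, row in enumerate(np.asarray(table)):
        for j, c in enumerate(row):
            y.extend([i] * int(c))
            x.extend([j] * int(c))
    return np.array(y), np.array(x)


class TestG2:
    def test_exact_independence_gives_zero(self):
        y, x = table_to_columns([[10, 10], [10, 10]])
        res = g2_test(y, x)
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == pytest.approx(1.0)
        assert res.independent is True

    def test_matches_brute_force_on_association_table(self):
        tab = [[30, 10], [10, 30]]
        y, x = table_to_columns(tab)
        res = g2_test(y, x)
        expected = g2_brute(tab)
        assert res.statistic == pytest.approx(expected, abs=1e-9)
        assert res.df == 1
        assert res.p_value == pytest.approx(chi2.sf(expected, 1))
        assert res.independent is False

    def test_reliability_threshold_arithmetic(self):
        # binary target, ternary x, two ternary conditioners: need 5*2*3*9=270
        rng = np.random.default_rng(0)
        y = rng.integers(0, 2, 100)
        x = rng.integers(0, 3, 100)
        z = [rng.integers(0, 3, 100), rng.integers(0, 3, 100)]
        res = g2_test(y, x, z)
        assert res.reliable is False
        assert res.independent is None

    def test_degenerate_target_raises(self):
        with pytest.raises(ValueError, match="degenerate target"):
            g2_test(np.zeros(50, dtype=int), np.arange(50) % 3)

    def test_conditioning_on_exact_duplicate_gives_independence(self):
        rng = np.random.default_rng(1)
        x = rng.integers(0, 3, 600)
        y = (x > 0).astype(int) ^ (rng.random(600) < 0.1).astype(int)
        res = g2_test(y, x, [x.copy()])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p_value == 1.0
        assert res.independent is True

    def test_missing_rows_dropped_pairwise(self):
        y = np.array([0, 1, 0, 1, 0, 1] * 10)
        x = np.array([0, 2, 0, 2, 0, 2] * 10)
        x2 = x.copy()
        x2[0] = -1  # MISSING sentinel
        full = g2_test(y, x)
        dropped = g2_test(y, x2)
        assert dropped.n == full.n - 1

    def test_permutation_invariance_of_marginal_test(self):
        rng = np.random.default_rng(3)
        y = rng.integers(0, 2, 300)
        x = rng.integers(0, 3, 300)
        perm = rng.permutation(300)
        a = g2_test(y, x)
        b = g2_test(y[perm], x[perm])
        assert a.statistic == pytest.approx(b.statistic, abs=1e-10)
        assert a.df == b.df

    @settings(deadline=None, max_examples=200)
    @given(
        st.lists(
            st.lists(st.integers(0, 40), min_size=2, max_size=4),
            min_size=2,
            max_size=3,
        ).filter(
            lambda rows: len({len(r) for r in rows}) == 1
            and sum(map(sum, rows)) > 0
            and sum(1 for r in rows if sum(r) > 0) >= 2
            and sum(1 for c in zip(*rows) if sum(c) > 0) >= 1
        )
    )
    def test_g2_equals_brute_force_on_random_tables(self, rows):
        tab = np.array(rows)
        y, x = table_to_columns(tab)
        if len(np.unique(y)) < 2:
            return
        res = g2_test(y, x)
        # brute force on the observed-level submatrix
        sub = tab[np.asarray(tab.sum(1) > 0)][:, np.asarray(tab.sum(0) > 0)]
        assert res.statistic == pytest.approx(g2_brute(sub), abs=1e-9)


class TestMaxConditioningSize:
    @pytest.mark.parametrize(
        "n,expected",
        [(1366, 3), (90, 1), (29, 0), (30, 0), (89, 0), (2430, 4)],
    )
    def test_log3_formula(self, n, expected):
        assert max_conditioning_size(n, 5, 2, 3, 3) == expected

    def test_invalid_arguments(self):
        with pytest.raises(ValueError):
            max_conditioning_size(0)


class TestHWE:
    def test_exact_proportions_statistic_zero(self):
        assert hwe_statistic(25, 50, 25) == pytest.approx(0.0, abs=1e-12)
        assert hwe_test(25, 50, 25) == pytest.approx(1.0)

    def test_no_heterozygotes_rejected(self):
        # p=q=0.5, n=100: chi2 = 25+50+25 = 100
        assert hwe_statistic(50, 0, 50) == pytest.approx(100.0)
        assert hwe_test(50, 0, 50) < 1e-5

    def test_statistic_scales_with_sample_size(self):
        a = hwe_statistic(30, 40, 30)
        b = hwe_statistic(300, 400, 300)
        assert b == pytest.approx(10 * a, rel=1e-12)

    def test_monomorphic_counts_fit_perfectly(self):
        assert hwe_test(0, 0, 80) == pytest.approx(1.0)


class TestMAF:
    def test_case_genotype_counts_give_48_percent(self):
        # counts hom-major=213, het=468, hom-minor=182 over 863 subjects
        col = counts_to_column(213, 468, 182)
        assert maf(col) == pytest.approx((2 * 182 + 468) / (2 * 863))
        assert round(100 * maf(col)) == 48

    def test_control_genotype_counts_give_25_percent(self):
        col = counts_to_column(662, 453, 66)
        assert maf(col) == pytest.approx((2 * 66 + 453) / (2 * 1181))
        assert round(100 * maf(col)) == 25

    def test_edge_columns(self):
        assert maf(np.zeros(10, dtype=np.int8)) == 0.0
        assert maf(np.ones(10, dtype=np.int8)) == 0.5
        with pytest.raises(ValueError):
            maf(np.full(5, -1, dtype=np.int8))


class TestLDR2:
    def test_complete_ld_contingency_pattern(self):
        # pooled cells: (0,2)x248, (1,1)x921, (2,0)x875 -> r^2 = 1
        a = np.concatenate([np.full(248, 0), np.full(921, 1), np.full(875, 2)])
        b = np.concatenate([np.full(248, 2), np.full(921, 1), np.full(875, 0)])
        assert ld_r2(a, b) == pytest.approx(1.0)

    def test_self_copy_is_one(self):
        rng = np.random.default_rng(0)
        a = rng.integers(0, 3, 200)
        assert ld_r2(a, a.copy()) == pytest.approx(1.0)

    def test_independent_snps_near_zero(self):
        rng = np.random.default_rng(1)
        a = rng.binomial(2, 0.3, 10000)
        b = rng.binomial(2, 0.3, 10000)
        assert ld_r2(a, b) < 0.01

    def test_monomorphic_errors(self):
        with pytest.raises(ValueError, match="monomorphic"):
            ld_r2(np.zeros(10, dtype=int), np.arange(10) % 3)


class TestHypergeom:
    def test_small_case_matches_closed_form(self):
        assert hypergeom_enrichment(10, 5, 4, 4) == pytest.approx(5 / 210)

    def test_k_zero_is_one(self):
        assert hypergeom_enrichment(100, 40, 10, 0) == pytest.approx(1.0)

    def test_bounds_checked(self):
        with pytest.raises(ValueError):
            hypergeom_enrichment(10, 5, 4, 5)

    @settings(deadline=None, max_examples=150)
    @given(st.data())
    def test_matches_exhaustive_enumeration_small_populations(self, data):
        N = data.draw(st.integers(1, 12))
        K = data.draw(st.integers(0, N))
        n = data.draw(st.integers(0, N))
        k = data.draw(st.integers(max(0, n - (N - K)), min(n, K)))
        hits = 0
        total = 0
        for draw in itertools.combinations(range(N), n):
            total += 1
            if sum(1 for i in draw if i < K) >= k:
                hits += 1
        assert hypergeom_enrichment(N, K, n, k) == pytest.approx(hits / total, abs=1e-12)


class TestBHFDR:
    def test_step_up_by_hand(self):
        # 0.04 > 3/4*0.05, 0.012 <= 2/4*0.05 -> reject the two smallest
        mask = bh_fdr([0.001, 0.012, 0.04, 0.9], q=0.05)
        assert list(mask) == [True, True, False, False]

    def test_all_ones_rejects_none(self):
        assert not bh_fdr([1.0] * 5, q=0.05).any()

    def test_single_p_reduces_to_alpha_test(self):
        assert bh_fdr([0.04], q=0.05).all()
        assert not bh_fdr([0.06], q=0.05).any()

    @settings(deadline=None, max_examples=100)
    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    def test_never_rejects_more_than_naive_qm_threshold(self, ps):
        q = 0.05
        mask = bh_fdr(ps, q)
        naive = sum(p <= q for p in ps)  # naive alpha=q thresholding
        assert mask.sum() <= naive
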