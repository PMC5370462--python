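from fractions import Fraction
from math import comb

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from dmrscan.stats_core import (
    ContingencyTable2x2,
    arcsine_t_test,
    bh_fdr,
    chi2_heterogeneity,
    chi2_heterogeneity_many,
    empirical_p,
    fisher_two_tailed,
)


def fisher_oracle(a, b, c, d):
    """Exact rational enumeration of the minimum-likelihood two-tailed p."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2
    if r1 == 0 or r2 == 0 or c1 == 0 or (b + d) == 0:
        return 1.0
    denom = comb(n, c1)
    obs = Fraction(comb(r1, a) * comb(r2, c), denom)
    total = Fraction(0)
    for k in range(max(0, c1 - r2), min(r1, c1) + 1):
        pk = Fraction(comb(r1, k) * comb(r2, c1 - k), denom)
        if pk <= obs:
            total += pk
    return float(min(total, Fraction(1)))


class TestFisherTwoTailed:
    def test_symmetric_table_is_one(self):
        assert fisher_two_tailed(ContingencyTable2x2(5, 5, 5, 5)) == 1.0

    def test_extreme_table_enumeration(self):
        # both extreme tables have probability 1/C(20,10)
        expected = 2 / comb(20, 10)
        assert fisher_two_tailed((10, 0, 0, 10)) == pytest.approx(
            expected, abs=1e-15
        )

    def test_zero_margin_degenerate(self):
        assert fisher_two_tailed((0, 0, 3, 7)) == 1.0
        assert fisher_two_tailed((3, 0, 7, 0)) == 1.0

    @given(
        st.integers(0, 12), st.integers(0, 12),
        st.integers(0, 12), st.integers(0, 12),
    )
    @settings(max_examples=200, deadline=None)
    def test_matches_enumeration_oracle(self, a, b, c, d):
        if a + b + c + d == 0:
            return
        assert fisher_two_tailed((a, b, c, d)) == pytest.approx(
            fisher_oracle(a, b, c, d), abs=1e-12
        )

    def test_matches_scipy_on_large_tables(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            a, b, c, d = rng.integers(0, 400, size=4)
            if min(a + b, c + d, a + c, b + d) == 0:
                continue
            ours = fisher_two_tailed((int(a), int(b), int(c), int(d)))
            ref = sps.fisher_exact([[a, b], [c, d]])[1]
            assert ours == pytest.approx(ref, rel=1e-6, abs=1e-12)

    def test_rejects_negative(self):
        with pytest.raises(ValueError):
            ContingencyTable2x2(-1, 2, 3, 4)


class TestChi2Heterogeneity:
    def test_identical_rows(self):
        stat, df, p = chi2_heterogeneity([(5, 5)] * 4)
        assert stat == 0 and df == 3 and p == 1.0

    def test_opposite_rows(self):
        stat, df, p = chi2_heterogeneity([(10, 0), (0, 10)])
        assert stat == pytest.approx(20.0)
        assert df == 1
        assert p == pytest.approx(sps.chi2.sf(20.0, 1))

    def test_single_row_errors(self):
        with pytest.raises(ValueError, match="insufficient"):
            chi2_heterogeneity([(5, 5)])

    def test_zero_column_margin(self):
        stat, df, p = chi2_heterogeneity([(5, 0), (3, 0)])
        assert stat == 0.0 and p == 1.0

    def test_row_order_invariance(self):
        rows = [(8, 2), (5, 5), (1, 9), (4, 6)]
        s1, _, p1 = chi2_heterogeneity(rows)
        s2, _, p2 = chi2_heterogeneity(rows[::-1])
        assert s1 == pytest.approx(s2) and p1 == pytest.approx(p2)

    def test_matches_scipy_contingency(self):
        rows = [(8, 2), (5, 5), (1, 9), (4, 6)]
        stat, df, p = chi2_heterogeneity(rows)
        ref = sps.chi2_contingency(np.array(rows), correction=False)
        assert stat == pytest.approx(ref.statistic)
        assert df == ref.dof
        assert p == pytest.approx(ref.pvalue)

    def test_vectorised_matches_scalar(self):
        rng = np.random.default_rng(1)
        meth = rng.integers(0, 30, size=(50, 4))
        unmeth = rng.integers(0, 30, size=(50, 4))
        stat_v, p_v = chi2_heterogeneity_many(meth, unmeth)
        for i in range(50):
            rows = list(zip(meth[i], unmeth[i]))
            if sum(m + u > 0 for m, u in rows) < 2:
                continue
            s, _, p = chi2_heterogeneity(rows)
            assert stat_v[i] == pytest.approx(s)
            assert p_v[i] == pytest.approx(p)


class TestBhFdr:
    def test_single_p(self):
        assert bh_fdr([0.05]) == pytest.approx([0.05])

    def test_step_up_example(self):
        # q_(i) = min_{j>=i} p_(j) * n / j: all collapse to 0.04
        assert bh_fdr([0.01, 0.02, 0.03, 0.04]) == pytest.approx([0.04] * 4)

    def test_all_ones(self):
        assert bh_fdr([1.0, 1.0, 1.0]) == pytest.approx([1.0] * 3)

    def test_out_of_range_errors(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=40))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_permutation_invariant(self, ps):
        q = bh_fdr(ps)
        order = np.argsort(ps, kind="stable")
        assert np.all(np.diff(q[order]) >= -1e-12)
        perm = np.random.default_rng(0).permutation(len(ps))
        q_perm = bh_fdr(np.asarray(ps)[perm])
        assert np.allclose(np.sort(q), np.sort(q_perm))


class TestEmpiricalP:
    def test_observed_beats_all(self):
        assert empirical_p(10.0, np.zeros(999), "greater") == pytest.approx(
            1 / 1000
        )

    def test_all_ties(self):
        assert empirical_p(1.0, np.ones(99), "greater") == 1.0
        assert empirical_p(1.0, np.ones(99), "less") == 1.0

    def test_median_observed(self):
        null = np.arange(99, dtype=float)  # 50 values >= 49
        assert empirical_p(49.0, null, "greater") == pytest.approx(51 / 100)

    def test_empty_null_errors(self):
        with pytest.raises(ValueError):
            empirical_p(1.0, [], "greater")

    def test_never_zero_and_bounded(self):
        rng = np.random.default_rng(2)
        null = rng.normal(size=500)
        for obs in (-10, 0, 10):
            p = empirical_p(obs, null, "greater")
            assert 0 < p <= 1


def welch_oracle(x, y):
    """Textbook Welch t-test on already-transformed values."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = len(x), len(y)
    t = (x.mean() - y.mean()) / np.sqrt(vx / nx + vy / ny)
    df = (vx / nx + vy / ny) ** 2 / (
        (vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1)
    )
    p = 2 * sps.t.sf(abs(t), df)
    return t, df, p


class TestArcsineTTest:
    def test_identical_groups(self):
        t, df, p = arcsine_t_test([0.5, 0.6, 0.7], [0.5, 0.6, 0.7])
        assert t == 0 and p == 1.0

    def test_separated_groups_significant(self):
        a, b = [0.2, 0.25, 0.3], [0.6, 0.65, 0.7]
        t, df, p = arcsine_t_test(a, b)
        ot, odf, op = welch_oracle(
            np.arcsin(np.sqrt(a)), np.arcsin(np.sqrt(b))
        )
        assert p < 0.05
        assert t == pytest.approx(ot)
        assert df == pytest.approx(odf)
        assert p == pytest.approx(op)

    def test_out_of_range(self):
        with pytest.raises(ValueError):
            arcsine_t_test([1.2, 0.5], [0.4, 0.5])

    def test_constant_equal_groups(self):
        _, _, p = arcsine_t_test([0.5, 0.5], [0.5, 0.5])
        assert p == 1.0
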