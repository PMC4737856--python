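"""Unit and property tests for the shared statistics."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ctcaller import stats

from _oracles import (
    fisher_two_sided_oracle,
    rank_sum_two_sided_oracle,
    spearman_rho_formula,
)


class TestFisher:
    @pytest.mark.parametrize(
        "table,expected",
        [
            ([[3, 1], [1, 3]], 34 / 70),
            ([[5, 0], [0, 5]], 2 / 252),
            ([[0, 0], [3, 4]], 1.0),  # zero margin: single possible table
            ([[2, 0], [5, 0]], 1.0),
        ],
    )
    def test_two_sided_examples(self, table, expected):
        assert stats.fisher_2x2(table).p_value == pytest.approx(expected, abs=1e-12)

    def test_one_sided_tails(self):
        res_g = stats.fisher_2x2([[5, 0], [0, 5]], sidedness="greater")
        res_l = stats.fisher_2x2([[5, 0], [0, 5]], sidedness="less")
        assert res_g.p_value == pytest.approx(1 / 252, abs=1e-12)
        assert res_l.p_value == pytest.approx(1.0)

    def test_matches_exact_enumeration_small(self):
        for n_total in range(1, 16):
            for r1 in range(n_total + 1):
                for c1 in range(n_total + 1):
                    kmin, ps = fisher_two_sided_oracle(n_total, r1, c1)
                    for i, p_exact in enumerate(ps):
                        a = kmin + i
                        t = [[a, r1 - a], [c1 - a, n_total - r1 - c1 + a]]
                        assert stats.fisher_2x2(t).p_value == pytest.approx(
                            p_exact, abs=1e-10
                        )

    def test_negative_cell_rejected(self):
        with pytest.raises(ValueError):
            stats.fisher_2x2([[1, -1], [0, 2]])

    @given(st.lists(st.integers(0, 12), min_size=4, max_size=4))
    @settings(deadline=None, max_examples=50, derandomize=True)
    def test_symmetric_in_flag_swap(self, cells):
        # swapping the two binary factors transposes the table and must
        # leave the two-sided p unchanged
        a, b, c, d = cells
        p1 = stats.fisher_2x2([[a, b], [c, d]]).p_value
        p2 = stats.fisher_2x2([[a, c], [b, d]]).p_value
        assert p1 == pytest.approx(p2, rel=1e-9)


class TestBHAdjust:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ([0.01, 0.02, 0.03, 0.04], [0.04, 0.04, 0.04, 0.04]),
            ([0.005], [0.005]),
            ([0.02, 0.8], [0.04, 0.8]),
        ],
    )
    def test_hand_examples(self, raw, expected):
        assert stats.bh_adjust(raw) == pytest.approx(expected)

    def test_rejects_out_of_range(self):
        with pytest.raises(ValueError):
            stats.bh_adjust([0.5, 1.5])

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=30))
    @settings(deadline=None, max_examples=100, derandomize=True)
    def test_dominates_raw_and_is_monotone(self, raw):
        adj = stats.bh_adjust(raw)
        assert np.all(adj >= np.asarray(raw) - 1e-12)
        assert np.all(adj <= 1.0 + 1e-12)
        order = np.argsort(raw)
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_decisions_match_step_up_oracle(self):
        # q_i <= alpha must reproduce the classic step-up rejection set
        rng = np.random.default_rng(0)
        for alpha in (0.01, 0.05, 0.1):
            raw = rng.uniform(0, 1, 60) ** 3
            adj = stats.bh_adjust(raw)
            order = np.argsort(raw)
            m = len(raw)
            k_max = 0
            for rank, idx in enumerate(order, start=1):
                if raw[idx] <= alpha * rank / m:
                    k_max = rank
            expected = np.zeros(m, bool)
            expected[order[:k_max]] = True
            assert np.array_equal(adj <= alpha, expected)


class TestRankSum:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ([1, 2, 3], [4, 5, 6], 2 / 20),
            ([1, 2], [1, 2], 1.0),
        ],
    )
    def test_exact_examples(self, a, b, expected):
        assert stats.rank_sum_test(a, b).p_value == pytest.approx(expected)

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            stats.rank_sum_test([], [1.0])

    @pytest.mark.parametrize("n1,n2,seed", [(3, 3, 0), (4, 5, 1), (2, 9, 2), (6, 6, 3)])
    def test_matches_label_enumeration(self, n1, n2, seed):
        rng = np.random.default_rng(seed)
        # integer draws force ties, exercising average ranks
        a = rng.integers(0, 6, n1).astype(float)
        b = rng.integers(0, 6, n2).astype(float)
        expected = rank_sum_two_sided_oracle(a, b)
        assert stats.rank_sum_test(a, b).p_value == pytest.approx(expected)

    def test_null_large_sample_p_not_small(self):
        rng = np.random.default_rng(42)
        n_small = 0
        for _ in range(100):
            a = rng.normal(size=50)
            b = rng.normal(size=50)
            if stats.rank_sum_test(a, b).p_value <= 0.01:
                n_small += 1
        # a calibrated test yields p <= 0.01 about once per 100 draws;
        # allow binomial slack
        assert n_small <= 2

    @given(st.data())
    @settings(deadline=None, max_examples=40, derandomize=True)
    def test_monotone_transform_invariance(self, data):
        a = data.draw(st.lists(st.integers(0, 20), min_size=2, max_size=6))
        b = data.draw(st.lists(st.integers(0, 20), min_size=2, max_size=6))
        p1 = stats.rank_sum_test(a, b).p_value
        fa = [np.exp(0.3 * x) for x in a]
        fb = [np.exp(0.3 * x) for x in b]
        assert stats.rank_sum_test(fa, fb).p_value == pytest.approx(p1)


class TestSpearman:
    def test_monotone_limits(self):
        assert stats.spearman_corr([1, 2, 3], [10, 20, 30]).statistic == pytest.approx(1.0)
        assert stats.spearman_corr([1, 2, 3], [30, 20, 10]).statistic == pytest.approx(-1.0)

    def test_d2_formula_example(self):
        res = stats.spearman_corr([1, 2, 3, 4], [1, 3, 2, 4])
        assert res.statistic == pytest.approx(0.8)
        assert res.statistic == pytest.approx(
            spearman_rho_formula([1, 2, 3, 4], [1, 3, 2, 4])
        )

    def test_exact_small_p_is_permutation_fraction(self):
        # for perfectly concordant n=3, only 2 of 6 orderings reach |rho|=1
        res = stats.spearman_corr([1, 2, 3], [10, 20, 30])
        assert res.p_value == pytest.approx(2 / 6)

    def test_input_validation(self):
        with pytest.raises(ValueError):
            stats.spearman_corr([1, 2], [1, 2])
        with pytest.raises(ValueError):
            stats.spearman_corr([1, 2, 3], [1, 2])

    def test_constant_input_flagged(self):
        res = stats.spearman_corr([1, 1, 1, 1], [1, 2, 3, 4])
        assert np.isnan(res.statistic)
        assert res.p_value == 1.0

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=30)
        y = rng.normal(size=30)
        r1 = stats.spearman_corr(x, y)
        r2 = stats.spearman_corr(np.exp(x), y**3)
        assert r1.statistic == pytest.approx(r2.statistic)
        assert r1.p_value == pytest.approx(r2.p_value)


class TestLinearFit:
    def test_exact_fit(self):
        x = [0.0, 1.0, 2.0, 3.0]
        y = [-5.0 * v for v in x]
        beta, res = stats.linear_fit(y, x)
        assert beta == pytest.approx(-5.0)
        assert res.direction == "depleted"

    def test_constant_response(self):
        beta, res = stats.linear_fit([2.0] * 10, list(range(10)))
        assert beta == 0.0
        assert res.p_value == 1.0

    def test_collinear_raises(self):
        with pytest.raises(np.linalg.LinAlgError):
            stats.linear_fit([1.0, 2.0, 3.0, 4.0], [1.0, 1.0, 1.0, 1.0])

    def test_covariate_adjustment_recovers_slope(self):
        # two cancer types with different intercepts must not bias the slope
        rng = np.random.default_rng(11)
        n_hit = 0
        for _ in range(100):
            x = rng.uniform(0, 1, 500)
            labels = np.where(np.arange(500) < 250, "A", "B")
            y = -5.0 * x + np.where(labels == "A", 0.0, 4.0) + rng.normal(0, 1, 500)
            beta, _ = stats.linear_fit(y, x, labels)
            if abs(beta - (-5.0)) <= 0.5:
                n_hit += 1
        assert n_hit >= 95
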