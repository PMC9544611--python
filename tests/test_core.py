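"""Heterozygosity statistics, the F_ST bound, and the normalized ratio.

The closed-form bound is validated against the constructive maximizing
configuration, which is the authoritative oracle: it is an explicit Q
matrix whose F_ST is evaluated with the same public heterozygosity
formulas that any caller uses.
"""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from fstratio import (
    MonomorphicError,
    QMatrix,
    fst,
    fst_max_closed,
    fst_max_constructive,
    fst_ratio,
    het_total,
    het_within,
    most_frequent_mean,
    ratio_batch,
)
from .conftest import random_qmatrix


class TestHeterozygosities:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            ([[1, 0], [0, 1]], 0.0),
            ([[0.5, 0.5], [0.5, 0.5]], 0.5),
            ([[1, 0], [0.5, 0.5]], 0.25),
        ],
    )
    def test_het_within_hand_values(self, matrix, expected):
        assert het_within(np.array(matrix, float)) == pytest.approx(expected, abs=1e-15)

    @pytest.mark.parametrize(
        "matrix,expected",
        [
            ([[1, 0], [0, 1]], 0.5),
            ([[1, 0], [1, 0]], 0.0),
            ([[1, 0], [0.5, 0.5]], 0.375),
        ],
    )
    def test_het_total_hand_values(self, matrix, expected):
        assert het_total(np.array(matrix, float)) == pytest.approx(expected, abs=1e-15)

    def test_brute_force_oracle(self):
        """Both formulas match explicit double-loop summation."""
        rng = np.random.default_rng(2)
        q = random_qmatrix(rng, i_count=6, k_count=4)
        v = q.values
        i_count, k_count = v.shape
        hs = 1 - sum(v[i, k] ** 2 for i in range(i_count) for k in range(k_count)) / i_count
        ht = 1 - sum((sum(v[i, k] for i in range(i_count)) / i_count) ** 2
                     for k in range(k_count))
        assert het_within(q) == pytest.approx(hs, abs=1e-12)
        assert het_total(q) == pytest.approx(ht, abs=1e-12)


class TestFst:
    @pytest.mark.parametrize(
        "matrix,expected",
        [
            ([[1, 0], [0, 1]], 1.0),
            ([[0.3, 0.7], [0.3, 0.7]], 0.0),
            ([[1, 0], [0.5, 0.5]], 1 / 3),
        ],
    )
    def test_hand_values(self, matrix, expected):
        assert fst(np.array(matrix, float)) == pytest.approx(expected, abs=1e-15)

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicError):
            fst(np.array([[1.0, 0.0], [1.0, 0.0]]))


class TestMostFrequentMean:
    @pytest.mark.parametrize(
        "matrix,m,sigma1",
        [
            ([[1, 0], [0, 1]], 0.5, 1.0),
            ([[1, 0], [0.5, 0.5]], 0.75, 1.5),
        ],
    )
    def test_hand_values(self, matrix, m, sigma1):
        got_m, got_s = most_frequent_mean(np.array(matrix, float))
        assert got_m == pytest.approx(m) and got_s == pytest.approx(sigma1)

    def test_tie_value_identical_under_any_choice(self):
        m, _ = most_frequent_mean(np.array([[0.5, 0.5], [0.5, 0.5]]))
        assert m == 0.5


class TestBound:
    @pytest.mark.parametrize(
        "i_count,m,expected",
        [
            (2, 0.5, 1.0),        # integer sigma1 = 1
            (5, 0.4, 1.0),        # integer sigma1 = 2
            (2, 0.75, 1 / 3),     # sigma1 = 1.5
            (2, 0.25, 1 / 3),     # sigma1 = 0.5, J = 2
            (3, 0.5, 8 / 11),     # sigma1 = 1.5
        ],
    )
    def test_closed_form_hand_values(self, i_count, m, expected):
        assert fst_max_closed(i_count, m) == pytest.approx(expected, abs=1e-12)

    def test_undefined_at_m_one(self):
        with pytest.raises(MonomorphicError):
            fst_max_closed(4, 1.0)

    def test_requires_two_individuals(self):
        with pytest.raises(ValueError):
            fst_max_closed(1, 0.5)

    @pytest.mark.parametrize(
        "i_count,m,witness_expected",
        [
            (2, 0.75, [[1, 0], [0.5, 0.5]]),
            (2, 0.25, [[0.5, 0.5, 0, 0], [0, 0, 0.5, 0.5]]),
        ],
    )
    def test_constructive_witnesses(self, i_count, m, witness_expected):
        value, witness = fst_max_constructive(i_count, m)
        assert value == pytest.approx(1 / 3, abs=1e-12)
        assert np.allclose(witness.values, np.array(witness_expected, float))

    def test_integer_sigma_witness(self):
        value, witness = fst_max_constructive(3, 2 / 3)
        assert value == 1.0
        assert het_within(witness) == 0.0  # every row fully in one cluster
        assert np.sum(witness.values[:, 0] == 1.0) == 2

    def test_witness_mean_matches_m(self):
        for i_count, m in [(4, 0.3), (7, 0.61), (5, 0.13), (3, 0.99)]:
            _, witness = fst_max_constructive(i_count, m)
            assert witness.values.mean(axis=0).max() == pytest.approx(m, abs=1e-12)

    def test_closed_equals_constructive_on_grid(self):
        """Oracle equivalence over I in 2..10, 50+ interior M values each."""
        worst = 0.0
        for i_count in range(2, 11):
            for m in np.linspace(1 / i_count, 1, 54)[1:-1]:
                closed = fst_max_closed(i_count, m)
                value, _ = fst_max_constructive(i_count, m)
                worst = max(worst, abs(closed - value))
        assert worst <= 1e-12

    def test_small_sigma_branch_matches_constructive(self):
        """sigma1 < 1 needs K > I; exercised through M = s/I, s < 1."""
        for i_count in (2, 3, 6, 10):
            for s in np.linspace(0.05, 0.95, 19):
                closed = fst_max_closed(i_count, s / i_count)
                value, _ = fst_max_constructive(i_count, s / i_count)
                assert closed == pytest.approx(value, abs=1e-12)

    def test_bound_dominates_random_matrices(self):
        """No random matrix exceeds the bound at its own (I, M).  Slack of
        1e-9 absorbs cancellation noise in both sides near M -> 1."""
        rng = np.random.default_rng(7)
        for _ in range(300):
            q = random_qmatrix(rng)
            m, _ = most_frequent_mean(q)
            assert fst(q) <= fst_max_closed(q.n_individuals, m) + 1e-9

    def test_peaks_at_integer_sigma(self):
        """The bound approaches 1 as sigma1 approaches any integer in (1, I)."""
        i_count = 6
        for target in (2, 3, 4, 5):
            for eps in (1e-3, 1e-5):
                for s in (target - eps, target + eps):
                    assert fst_max_closed(i_count, s / i_count) > 1 - 5e-3
        assert fst_max_closed(i_count, 2.5 / 6) < 0.9


class TestRatio:
    def test_maximizing_matrix_has_ratio_one(self, simple_q):
        r = fst_ratio(simple_q)
        assert r.fst == pytest.approx(1 / 3, abs=1e-15)
        assert r.fst_max == pytest.approx(1 / 3, abs=1e-12)
        assert r.ratio == pytest.approx(1.0, abs=1e-12)

    def test_identical_rows_give_zero(self):
        q = QMatrix(np.tile([0.3, 0.2, 0.5], (8, 1)))
        assert fst_ratio(q).ratio == 0.0

    def test_constructive_witnesses_score_one(self):
        for i_count, m in [(2, 0.75), (3, 0.5), (5, 0.44), (4, 2 / 4), (6, 0.09)]:
            _, witness = fst_max_constructive(i_count, m)
            assert fst_ratio(witness).ratio == pytest.approx(1.0, abs=1e-9)

    def test_monomorphic_raises(self):
        with pytest.raises(MonomorphicError):
            fst_ratio(np.array([[0.0, 1.0], [0.0, 1.0]]))

    def test_result_invariants_random(self):
        rng = np.random.default_rng(21)
        for _ in range(200):
            r = fst_ratio(random_qmatrix(rng))
            assert 0 <= r.hs <= r.ht <= 1
            assert 0 <= r.fst <= r.fst_max <= 1
            assert 0 <= r.ratio <= 1
            assert r.sigma1 == pytest.approx(r.i_count * r.m)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_symmetry_invariances(self, seed):
        """Row permutation, column permutation, and an appended all-zero
        column leave F_ST, M and the ratio unchanged."""
        rng = np.random.default_rng(seed)
        q = random_qmatrix(rng)
        base = fst_ratio(q)
        v = q.values
        permuted = v[rng.permutation(v.shape[0])][:, rng.permutation(v.shape[1])]
        padded = np.hstack([v, np.zeros((v.shape[0], 1))])
        for variant in (permuted, padded):
            r = fst_ratio(QMatrix(variant))
            assert r.fst == pytest.approx(base.fst, abs=1e-12)
            assert r.m == pytest.approx(base.m, abs=1e-12)
            assert r.ratio == pytest.approx(base.ratio, abs=1e-9)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(seed=st.integers(0, 2**31 - 1))
    def test_ratio_zero_iff_identical_rows(self, seed):
        rng = np.random.default_rng(seed)
        q = random_qmatrix(rng)
        rows_identical = bool(np.all(q.values == q.values[0]))
        assert (fst_ratio(q).ratio == 0.0) == rows_identical


class TestRatioBatch:
    def test_matches_scalar_path(self):
        rng = np.random.default_rng(3)
        qs = np.stack([random_qmatrix(rng, 5, 3).values for _ in range(20)])
        batch = ratio_batch(qs)
        single = [fst_ratio(qs[i]).ratio for i in range(20)]
        assert np.allclose(batch, single, atol=1e-12)

    def test_degenerate_policies(self):
        mono = np.array([[[1.0, 0.0], [1.0, 0.0]]])
        with pytest.raises(MonomorphicError):
            ratio_batch(mono, degenerate="error")
        assert ratio_batch(mono, degenerate="zero")[0] == 0.0
        assert np.isnan(ratio_batch(mono, degenerate="nan")[0])
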