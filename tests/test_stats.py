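"""Integrative test: statistics, permutations, empirical p, Stouffer, calls."""

import math

import numpy as np
import pandas as pd
import pytest
import scipy.stats as ss
from hypothesis import given
from hypothesis import strategies as st

from permdeg import (
    DEGThresholds,
    LogExpressionMatrix,
    build_null,
    call_degs,
    empirical_p,
    enumerate_splits,
    gene_statistics,
    integrative_test,
    stouffer_combine,
)
from permdeg.errors import DesignError, ValidationError


def _logmat(values: np.ndarray, labels=("a", "a", "b", "b")) -> LogExpressionMatrix:
    values = np.atleast_2d(np.asarray(values, dtype=float))
    samples = [f"s{i}" for i in range(values.shape[1])]
    return LogExpressionMatrix(
        pd.DataFrame(values, index=[f"g{i}" for i in range(values.shape[0])],
                     columns=samples),
        pd.Series(list(labels), index=samples),
    )


class TestGeneStatistics:
    def test_hand_example_pooled_variance(self):
        # group1 = (2, 4), group2 = (1, 3): lfc = -1; sample variances are
        # both 2, pooled s2 = 2, t = -1 / sqrt(2 * (1/2 + 1/2)) = -1/sqrt(2)
        lm = _logmat([[2.0, 4.0, 1.0, 3.0]])
        out = gene_statistics(lm)
        assert out["log2fc"].iloc[0] == pytest.approx(-1.0, abs=1e-12)
        assert out["t_stat"].iloc[0] == pytest.approx(-1.0 / math.sqrt(2), abs=1e-12)
        ref = ss.ttest_ind([1.0, 3.0], [2.0, 4.0], equal_var=True)
        assert out["t_stat"].iloc[0] == pytest.approx(ref.statistic, abs=1e-12)

    def test_matches_scipy_on_random_cases(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            n1 = rng.integers(2, 5)
            n2 = rng.integers(2, 5)
            x = rng.normal(size=n1 + n2) * rng.uniform(0.5, 3)
            labels = ["a"] * n1 + ["b"] * n2
            lm = _logmat(x, labels=labels)
            out = gene_statistics(lm)
            ref = ss.ttest_ind(x[n1:], x[:n1], equal_var=True)
            assert out["t_stat"].iloc[0] == pytest.approx(ref.statistic, abs=1e-10)

    def test_identical_groups_zero_statistics(self):
        lm = _logmat([[3.0, 3.0, 3.0, 3.0]])
        out = gene_statistics(lm)
        assert out["log2fc"].iloc[0] == 0.0
        assert out["t_stat"].iloc[0] == 0.0  # floored variance, zero numerator

    def test_label_swap_negates_statistics(self):
        # exchanging group roles = putting the former second group first
        rng = np.random.default_rng(2)
        vals = rng.normal(size=(20, 4))
        a = gene_statistics(_logmat(vals, labels=("a", "a", "b", "b")))
        b = gene_statistics(
            _logmat(vals[:, [2, 3, 0, 1]], labels=("b", "b", "a", "a"))
        )
        np.testing.assert_allclose(a["t_stat"], -b["t_stat"], atol=1e-12)
        np.testing.assert_allclose(a["log2fc"], -b["log2fc"], atol=1e-12)

    def test_single_replicate_group_rejected(self):
        with pytest.raises(DesignError):
            gene_statistics(_logmat([[1.0, 2.0, 3.0]], labels=("a", "b", "b")))


class TestEnumerateSplits:
    def test_two_vs_two_counts(self):
        sp = enumerate_splits(["a", "a", "b", "b"])
        assert sp.n_assignments == 6  # C(4, 2)
        assert sp.n_retained == 2  # identity and swap-duplicates removed
        for mask in sp.retained:
            assert mask.sum() == 2

    def test_three_vs_two_counts(self):
        sp = enumerate_splits(["a", "a", "a", "b", "b"])
        assert sp.n_assignments == 10  # C(5, 2)
        assert sp.n_retained == 9  # only the identity removed (unbalanced)

    def test_one_vs_one_design_error(self):
        with pytest.raises(DesignError):
            enumerate_splits(["a", "b"])

    def test_monte_carlo_fallback_is_seeded(self):
        labels = ["a"] * 8 + ["b"] * 8  # C(16, 8) = 12870 > cap
        sp1 = enumerate_splits(labels, max_exhaustive=10_000, n_permutations=50, seed=4)
        sp2 = enumerate_splits(labels, max_exhaustive=10_000, n_permutations=50, seed=4)
        assert not sp1.exhaustive
        assert sp1.n_retained == 50
        observed = tuple([False] * 8 + [True] * 8)
        for m1, m2 in zip(sp1.retained, sp2.retained):
            np.testing.assert_array_equal(m1, m2)
            assert tuple(m1) != observed and tuple(~m1) != observed


class TestBuildNull:
    def test_pooled_size_arithmetic(self, gaussian_logmat):
        sp = enumerate_splits(gaussian_logmat.group_labels)
        null = build_null(gaussian_logmat, sp)
        assert null.size == 200 * 2
        assert null.null_t.shape == (400,)
        assert null.null_lfc.shape == (400,)

    def test_constant_matrix_all_zero_null(self):
        lm = _logmat(np.full((10, 4), 2.5))
        null = build_null(lm, enumerate_splits(lm.group_labels))
        assert np.all(null.null_t == 0.0)
        assert np.all(null.null_lfc == 0.0)

    def test_null_symmetric_about_zero(self, gaussian_logmat):
        null = build_null(
            gaussian_logmat, enumerate_splits(gaussian_logmat.group_labels)
        )
        se = null.null_lfc.std() / np.sqrt(null.size)
        assert abs(null.null_lfc.mean()) <= 3 * se


class TestEmpiricalP:
    def test_count_based_oracle(self):
        assert empirical_p(1.5, np.array([-2.0, -1.0, 1.0, 2.0])) == pytest.approx(0.6)

    def test_zero_observed_gives_one(self):
        assert empirical_p(0.0, np.array([-2.0, -1.0, 1.0, 2.0])) == 1.0

    def test_smoothing_floor(self):
        null = np.arange(1, 100, dtype=float)
        assert empirical_p(1e9, null) == pytest.approx(1.0 / 100.0)

    def test_empty_null_rejected(self):
        with pytest.raises(ValidationError):
            empirical_p(1.0, np.array([]))

    @given(
        st.lists(st.floats(-50, 50), min_size=1, max_size=40),
        st.floats(-60, 60),
    )
    def test_on_grid_and_matches_bruteforce(self, null, obs):
        null_arr = np.asarray(null)
        p = empirical_p(obs, null_arr)
        n = len(null)
        brute = (np.sum(np.abs(null_arr) >= abs(obs)) + 1) / (n + 1)
        assert p == pytest.approx(brute, abs=1e-12)
        assert round(p * (n + 1)) == pytest.approx(p * (n + 1), abs=1e-9)


class TestStouffer:
    def test_half_half_fixed_point(self):
        p, z1, z2 = stouffer_combine(0.5, 0.5)
        assert p == pytest.approx(0.5, abs=1e-12)
        assert z1 == pytest.approx(0.0, abs=1e-12)

    def test_closed_form_005(self):
        # z = sqrt(2) * Phi^-1(0.95) = 2.3261...; 1 - Phi(z) = 0.0100
        p, *_ = stouffer_combine(0.05, 0.05)
        assert p == pytest.approx(0.0100, abs=1e-4)
        ref = ss.combine_pvalues([0.05, 0.05], method="stouffer").pvalue
        assert p == pytest.approx(ref, abs=1e-12)

    def test_monotone_in_each_argument(self):
        p_strong, *_ = stouffer_combine(0.01, 0.5)
        p_weak, *_ = stouffer_combine(0.05, 0.5)
        assert p_strong < p_weak

    def test_non_finite_input_rejected(self):
        with pytest.raises(ValidationError):
            stouffer_combine(np.nan, 0.5)

    @given(st.floats(0.001, 0.999), st.floats(0.001, 0.999))
    def test_symmetric_and_in_unit_interval(self, p1, p2):
        a, *_ = stouffer_combine(p1, p2)
        b, *_ = stouffer_combine(p2, p1)
        assert a == pytest.approx(b, rel=1e-12)
        assert 0.0 < a < 1.0


class TestCallDegs:
    @pytest.mark.parametrize(
        "p,lfc,expected,direction",
        [
            (0.04, 0.60, True, "up"),
            (0.04, 0.50, False, "none"),  # fails the 1.5-fold cutoff
            (0.051, -2.0, False, "none"),  # boundary: <= 0.05 is inclusive
            (0.05, 0.58, True, "up"),  # both boundaries inclusive
            (0.05, -0.58, True, "down"),
        ],
    )
    def test_dual_threshold(self, p, lfc, expected, direction):
        stats = pd.DataFrame(
            {"gene_id": ["g"], "log2fc": [lfc], "p_combined": [p]}
        )
        out = call_degs(stats, DEGThresholds())
        assert bool(out["is_deg"].iloc[0]) is expected
        assert out["direction"].iloc[0] == direction


class TestIntegrativeTest:
    def test_p_values_on_grid(self, gaussian_logmat):
        res = integrative_test(gaussian_logmat)
        n = res.null_summary["null_size"]
        for col in ("p_t", "p_lfc"):
            k = res.table[col] * (n + 1)
            np.testing.assert_allclose(k, np.round(k), atol=1e-8)

    def test_deg_flag_consistent_with_thresholds(self, gaussian_logmat):
        res = integrative_test(gaussian_logmat)
        t = res.table
        expected = (t["p_combined"] <= 0.05) & (t["log2fc"].abs() >= 0.58)
        assert (t["is_deg"] == expected).all()
        assert res.n_up + res.n_down == res.n_deg

    def test_label_swap_leaves_calls_invariant(self, gaussian_logmat):
        res_a = integrative_test(gaussian_logmat)
        # swap group roles by putting the b-samples first
        swapped_cols = ["b_1", "b_2", "a_1", "a_2"]
        flipped = LogExpressionMatrix(
            gaussian_logmat.values[swapped_cols],
            gaussian_logmat.group_labels[swapped_cols],
        )
        res_b = integrative_test(flipped)
        np.testing.assert_allclose(
            res_a.table["t_stat"], -res_b.table["t_stat"], atol=1e-12
        )
        np.testing.assert_allclose(res_a.table["p_t"], res_b.table["p_t"], atol=1e-12)
        np.testing.assert_allclose(
            res_a.table["p_combined"], res_b.table["p_combined"], atol=1e-12
        )
        assert (res_a.table["is_deg"] == res_b.table["is_deg"]).all()

    def test_per_gene_scope_uses_coarse_grid(self, gaussian_logmat):
        res = integrative_test(gaussian_logmat, null_scope="per_gene")
        assert res.null_summary["null_size"] == 2  # two retained splits
        assert set(np.round(res.table["p_t"] * 3).astype(int)) <= {1, 2, 3}

    def test_bh_adjustment_is_monotone_and_used_for_calls(self, gaussian_logmat):
        res = integrative_test(gaussian_logmat, bh=True)
        t = res.table
        assert (t["p_combined_bh"] >= t["p_combined"] - 1e-12).all()
        expected = (t["p_combined_bh"] <= 0.05) & (t["log2fc"].abs() >= 0.58)
        assert (t["is_deg"] == expected).all()

    def test_counts_input_accepted(self, small_counts):
        res = integrative_test(small_counts)
        assert len(res.table) == small_counts.n_genes
        assert res.group_order == ("wt", "ko")
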