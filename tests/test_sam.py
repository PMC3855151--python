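import math
from itertools import combinations

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirsig.preprocess import ExpressionMatrix, log_transform, normalize_to_reference
from mirsig.sam import (
    SamConfig,
    choose_s0,
    fold_changes,
    permutation_null,
    q_values,
    sam_analysis,
    sam_statistic,
    select_signature,
)
from mirsig.synthetic import CohortSpec, simulate_cohort


def _mask(n_case, n_ctrl):
    return np.concatenate([np.ones(n_case, bool), np.zeros(n_ctrl, bool)])


class TestSamStatistic:
    def test_hand_computed_pooled_se(self):
        # case [1,2,3] vs control [3,4,5]: pooled SSQ=4, df=4,
        # s = sqrt((1/3+1/3)*1) = 0.81650, d = -2/s = -2.4495
        x = np.array([[1.0, 2, 3, 3, 4, 5]])
        d = sam_statistic(x, _mask(3, 3), s0=0.0)
        assert d[0] == pytest.approx(-2.4495, abs=1e-4)

    def test_identical_groups_give_zero(self):
        x = np.array([[1.0, 2, 3, 1, 2, 3]])
        assert sam_statistic(x, _mask(3, 3), 0.0)[0] == pytest.approx(0.0)

    def test_label_swap_negates(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=(20, 10))
        case = _mask(5, 5)
        np.testing.assert_allclose(
            sam_statistic(x, case, 0.1), -sam_statistic(x, ~case, 0.1), rtol=1e-12
        )

    @given(c=st.floats(-3, 3))
    def test_invariant_to_global_shift(self, c):
        rng = np.random.default_rng(1)
        x = rng.normal(size=(15, 8))
        case = _mask(4, 4)
        np.testing.assert_allclose(
            sam_statistic(x, case, 0.05), sam_statistic(x + c, case, 0.05), atol=1e-10
        )

    def test_insufficient_group_values_yield_nan(self):
        x = np.array([[1.0, np.nan, np.nan, 2, 3, 4], [1, 2, 3, 4, 5, 6]])
        d = sam_statistic(x, _mask(3, 3), 0.0)
        assert np.isnan(d[0]) and np.isfinite(d[1])

    def test_all_rows_deficient_is_error(self):
        x = np.full((3, 6), np.nan)
        with pytest.raises(ValueError):
            sam_statistic(x, _mask(3, 3), 0.0)


class TestChooseS0:
    def test_too_few_features(self):
        x = np.random.default_rng(0).normal(size=(10, 8))
        with pytest.raises(ValueError, match="too few features"):
            choose_s0(x, _mask(4, 4))

    def test_equal_standard_errors_give_zero(self):
        # identical within-group deviations in every row -> all s_i equal
        row = np.array([1.0, 2, 3, 4, 2, 3, 4, 5])
        x = np.tile(row, (25, 1)) + np.arange(25)[:, None]  # shift rows, same s
        assert choose_s0(x, _mask(4, 4)) == 0.0

    def test_variance_dependent_inflation_selects_positive_s0(self):
        # a between-group offset with constant spread across features (a
        # technical batch shift) inflates |d| for low-variance rows when
        # s0=0; the dispersion-stabilizing choice must be positive
        rng = np.random.default_rng(7)
        scales = np.exp(rng.normal(-2, 1.5, size=300))
        x = rng.normal(size=(300, 12)) * scales[:, None]
        x[:, :6] += rng.normal(0, 0.05, size=300)[:, None]
        assert choose_s0(x, _mask(6, 6)) > 0


class TestPermutationNull:
    def test_exhaustive_enumeration_at_3v3(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=(30, 6))
        case = _mask(3, 3)
        cfg_a = SamConfig(n_permutations=20, seed=1)
        cfg_b = SamConfig(n_permutations=1000, seed=99)
        null_a, exp_a = permutation_null(x, case, cfg_a, s0=0.1)
        null_b, exp_b = permutation_null(x, case, cfg_b, s0=0.1)
        assert null_a.shape[0] == math.comb(6, 3) == 20
        # seed-independent once enumeration kicks in
        np.testing.assert_array_equal(null_a, null_b)
        np.testing.assert_allclose(exp_a, exp_b)

    def test_sampled_determinism(self):
        rng = np.random.default_rng(3)
        x = rng.normal(size=(25, 20))
        case = _mask(10, 10)
        cfg = SamConfig(n_permutations=50, seed=42)
        a, _ = permutation_null(x, case, cfg, s0=0.1)
        b, _ = permutation_null(x, case, cfg, s0=0.1)
        np.testing.assert_array_equal(a, b)

    def test_null_data_matches_expected_order_stats(self):
        rng = np.random.default_rng(4)
        x = rng.normal(size=(200, 12))
        case = _mask(6, 6)
        cfg = SamConfig(n_permutations=300, seed=0)
        s0 = choose_s0(x, case)
        null, expected = permutation_null(x, case, cfg, s0)
        observed = np.sort(sam_statistic(x, case, s0))
        # no group effect: observed order stats hug the permutation mean
        assert np.median(np.abs(observed - expected)) < 0.3


class TestQValues:
    def test_strong_signal_gets_zero_q(self):
        rng = np.random.default_rng(5)
        x = rng.normal(size=(100, 12)) * 0.3
        x[0, :6] += 10.0  # one hugely separated feature
        case = _mask(6, 6)
        cfg = SamConfig(n_permutations=300, seed=0)
        d = sam_statistic(x, case, 0.05)
        null, _ = permutation_null(x, case, cfg, 0.05)
        q = q_values(d, null)
        assert q[0] == 0.0

    def test_tied_scores_share_q(self):
        d = np.array([1.5, -1.5, 0.2])
        null = np.random.default_rng(0).normal(size=(100, 3))
        q = q_values(d, null)
        assert q[0] == q[1]

    def test_null_labels_give_large_q(self):
        rng = np.random.default_rng(6)
        x = rng.normal(size=(150, 12))
        case = _mask(6, 6)
        cfg = SamConfig(n_permutations=200, seed=0)
        d = sam_statistic(x, case, 0.1)
        null, _ = permutation_null(x, case, cfg, 0.1)
        q = q_values(d, null)
        assert np.median(q) > 0.5

    def test_monotone_in_abs_d(self):
        rng = np.random.default_rng(8)
        d = rng.normal(size=50)
        null = rng.normal(size=(80, 50))
        q = q_values(d, null)
        order = np.argsort(np.abs(d))
        assert np.all(np.diff(q[order]) <= 1e-12)


class TestFoldChange:
    def test_ratio_of_linear_means(self):
        expr = pd.DataFrame([[0.4, 0.4, 0.02, 0.02]], index=["m1"],
                            columns=["C1", "C2", "K1", "K2"])
        fc = fold_changes(expr, _mask(2, 2))
        assert fc["m1"] == pytest.approx(20.0)

    def test_scale_invariance(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.uniform(0.01, 1, size=(20, 8)))
        case = _mask(4, 4)
        np.testing.assert_allclose(
            fold_changes(expr, case), fold_changes(expr * 10, case), rtol=1e-12
        )

    def test_identical_groups_give_one(self):
        expr = pd.DataFrame([[0.3, 0.5, 0.3, 0.5]], index=["m1"])
        assert fold_changes(expr, _mask(2, 2))["m1"] == pytest.approx(1.0)


class TestSelection:
    def _result_with(self, fc, q, d=3.0):
        from mirsig.sam import SamResult

        table = pd.DataFrame({"d": [d], "s": [0.1], "mean_case": [fc], "mean_control": [1.0],
                              "fold_change": [fc], "q_value": [q]}, index=["m1"])
        return SamResult(table=table, s0=0.1, expected_order_stats=np.array([]))

    def test_passing_both_thresholds_selected_up(self):
        sel = select_signature(self._result_with(24.20, 0.0))
        assert sel.mirna_ids == ["m1"]
        assert sel.table.loc["m1", "direction"] == "up"

    def test_fold_change_threshold_is_strict(self):
        assert len(select_signature(self._result_with(7.9, 0.0))) == 0
        assert len(select_signature(self._result_with(8.0, 0.0))) == 0

    def test_q_threshold_rejects(self):
        assert len(select_signature(self._result_with(20.0, 0.01))) == 0

    def test_downregulated_selected_by_reciprocal_rule(self):
        sel = select_signature(self._result_with(1 / 20.0, 0.0, d=-3.0))
        assert sel.table.loc["m1", "direction"] == "down"


class TestEndToEnd:
    def test_planted_signature_recovered_on_synthetic_cohort(self):
        spec = CohortSpec(n_mirnas=250, n_planted=20, fc_range=(12.0, 20.0),
                          n_blocks=0, block_size=0, seed=11)
        ct, ann, gt = simulate_cohort(spec)
        em = normalize_to_reference(ct, "U6")
        cfg = SamConfig(n_permutations=300, seed=11)
        res = sam_analysis(em, (ann.groups == "UA").to_numpy(), cfg)
        sel = select_signature(res, cfg)
        hits = set(sel.mirna_ids) & set(gt.planted_fc)
        assert len(hits) >= 18
        assert len(set(sel.mirna_ids) - set(gt.planted_fc)) <= 1
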