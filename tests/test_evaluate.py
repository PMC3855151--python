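import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from mirsig.evaluate import (
    group_compare,
    hierarchical_cluster,
    logistic_adjusted,
    pca_classify,
    pca_reduce,
    roc_analysis,
)


# ---------------------------------------------------------------------------
# clustering


class TestHierarchicalCluster:
    def test_four_point_line_merges_close_pairs_first(self):
        # 1-D samples {0, 0.1, 10, 10.1}: average-linkage must join the two
        # tight pairs before bridging the big gap
        df = pd.DataFrame([[0.0, 0.1, 10.0, 10.1]] * 2, index=["m1", "m2"],
                          columns=["a", "b", "c", "d"])
        res = hierarchical_cluster(df)
        first_merge = set(res.sample_linkage[0, :2].astype(int))
        second_merge = set(res.sample_linkage[1, :2].astype(int))
        assert first_merge in ({0, 1}, {2, 3})
        assert second_merge in ({0, 1}, {2, 3})

    def test_duplicated_blocks_split_at_top(self):
        rng = np.random.default_rng(0)
        a = rng.normal(0, 0.1, size=(5, 3))
        b = rng.normal(8, 0.1, size=(5, 3))
        df = pd.DataFrame(np.hstack([a, b]), columns=list("abcxyz"))
        res = hierarchical_cluster(df)
        order = res.sample_order
        assert {tuple(order[:3]), tuple(order[3:])} == {
            tuple(sorted(["a", "b", "c"], key=order.index)),
            tuple(sorted(["x", "y", "z"], key=order.index)),
        }

    def test_sample_order_invariance_of_topology(self):
        rng = np.random.default_rng(1)
        df = pd.DataFrame(rng.normal(size=(6, 5)), columns=list("abcde"))
        res1 = hierarchical_cluster(df)
        perm = ["c", "a", "e", "b", "d"]
        res2 = hierarchical_cluster(df[perm])
        # same merge heights regardless of column order
        np.testing.assert_allclose(
            np.sort(res1.sample_linkage[:, 2]), np.sort(res2.sample_linkage[:, 2])
        )

    def test_constant_matrix_rejected(self):
        df = pd.DataFrame(np.ones((3, 4)))
        with pytest.raises(ValueError, match="zero variance"):
            hierarchical_cluster(df)


# ---------------------------------------------------------------------------
# PCA


class TestPca:
    def test_collinear_data_is_rank_one(self):
        t = np.linspace(0, 1, 6)
        df = pd.DataFrame([t, 2 * t, -0.5 * t], index=["m1", "m2", "m3"])
        res = pca_reduce(df, k=2)
        assert res.variance_explained[0] == pytest.approx(1.0)
        assert res.variance_explained.sum() <= 1.0 + 1e-12

    def test_scores_centered_and_ordered(self):
        rng = np.random.default_rng(2)
        df = pd.DataFrame(rng.normal(size=(10, 8)))
        res = pca_reduce(df, k=3)
        np.testing.assert_allclose(res.scores.mean(axis=0), 0, atol=1e-10)
        assert np.all(np.diff(res.variance_explained) <= 1e-12)

    def test_duplicated_sample_scores_identical(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(6, 4))
        df = pd.DataFrame(np.hstack([base, base[:, :1]]),
                          columns=["a", "b", "c", "d", "a2"])
        res = pca_reduce(df, k=2)
        np.testing.assert_allclose(res.scores.loc["a"], res.scores.loc["a2"], atol=1e-10)

    def test_k_too_large(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)))
        with pytest.raises(ValueError):
            pca_reduce(df, k=4)


class TestPcaClassify:
    def test_separated_clouds_fully_classified(self):
        rng = np.random.default_rng(4)
        a = rng.normal(0, 1, size=(30, 10))
        b = rng.normal(8, 1, size=(30, 10))  # 8 SD apart
        df = pd.DataFrame(np.hstack([a, b]))
        labels = pd.Series(["UA"] * 10 + ["CONTROL"] * 10, index=df.columns)
        res = pca_classify(pca_reduce(df, 3), labels)
        assert res["overall_rate"] == 1.0

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(5)
        df = pd.DataFrame(rng.normal(size=(20, 24)))
        rates = []
        for s in range(10):
            labels = pd.Series(np.random.default_rng(s).permutation(["A"] * 12 + ["B"] * 12),
                               index=df.columns)
            rates.append(pca_classify(pca_reduce(df, 3), labels)["overall_rate"])
        assert 0.25 < np.mean(rates) < 0.75

    def test_singleton_group_rejected(self):
        df = pd.DataFrame(np.random.default_rng(0).normal(size=(5, 4)))
        labels = pd.Series(["A", "A", "A", "B"], index=df.columns)
        with pytest.raises(ValueError, match="leave-one-out"):
            pca_classify(pca_reduce(df, 2), labels)

    def test_deterministic(self):
        rng = np.random.default_rng(6)
        df = pd.DataFrame(rng.normal(size=(8, 10)))
        labels = pd.Series(["A"] * 5 + ["B"] * 5, index=df.columns)
        p = pca_reduce(df, 3)
        assert pca_classify(p, labels) == pca_classify(p, labels)


# ---------------------------------------------------------------------------
# ROC


def _brute_force_auc(cases, controls):
    wins = sum((c > k) + 0.5 * (c == k) for c in cases for k in controls)
    return wins / (len(cases) * len(controls))


class TestRoc:
    def test_perfect_separation(self):
        res = roc_analysis(np.array([4.0, 5, 6, 1, 2, 3]),
                           np.array([True, True, True, False, False, False]))
        assert res.auc == 1.0
        assert res.sensitivity == 1.0 and res.specificity == 1.0
        assert 3.0 < res.cutoff <= 4.0

    def test_interleaved_three_quarters(self):
        # cases {2,4} vs controls {1,3}: 3 of 4 pairs concordant
        res = roc_analysis(np.array([2.0, 4, 1, 3]), np.array([True, True, False, False]))
        assert res.auc == pytest.approx(0.75)

    def test_label_swap_complement(self):
        rng = np.random.default_rng(7)
        v = rng.normal(size=12)
        case = np.array([True] * 5 + [False] * 7)
        assert roc_analysis(v, case).auc == pytest.approx(1 - roc_analysis(v, ~case).auc)

    @given(
        cases=st.lists(st.integers(0, 5), min_size=1, max_size=4),
        controls=st.lists(st.integers(0, 5), min_size=1, max_size=4),
    )
    def test_auc_equals_concordant_pair_count(self, cases, controls):
        v = np.array(cases + controls, dtype=float)
        mask = np.array([True] * len(cases) + [False] * len(controls))
        if np.ptp(v) == 0:
            return  # degenerate constant case handled separately
        assert roc_analysis(v, mask).auc == pytest.approx(_brute_force_auc(cases, controls))

    @given(st.sampled_from(["exp", "cube", "affine"]))
    def test_monotone_transform_invariance(self, kind):
        rng = np.random.default_rng(8)
        v = rng.normal(size=14)
        case = np.array([True] * 6 + [False] * 8)
        f = {"exp": np.exp, "cube": lambda x: x**3, "affine": lambda x: 3 * x + 1}[kind]
        assert roc_analysis(f(v), case).auc == pytest.approx(roc_analysis(v, case).auc)

    def test_constant_values_degenerate(self):
        res = roc_analysis(np.ones(6), np.array([True] * 3 + [False] * 3))
        assert res.auc == 0.5 and res.degenerate

    def test_one_empty_class_rejected(self):
        with pytest.raises(ValueError):
            roc_analysis(np.arange(4.0), np.array([True] * 4))

    def test_youden_tie_breaks_toward_specificity(self):
        # values 1,2 cases; 1,2 controls: J=0 everywhere; cutoff 2 gives
        # spec 0.5 > cutoff 1 spec 0
        res = roc_analysis(np.array([1.0, 2, 1, 2]), np.array([True, True, False, False]))
        assert res.specificity >= 0.5


# ---------------------------------------------------------------------------
# logistic regression


class TestLogistic:
    def _two_by_two(self, a, b, c, d):
        """Exposed: a events / b non-events; unexposed: c / d."""
        x = pd.Series([1.0] * (a + b) + [0.0] * (c + d))
        y = pd.Series([1.0] * a + [0.0] * b + [1.0] * c + [0.0] * d)
        return x, y

    def test_saturated_two_by_two_cross_product(self):
        x, y = self._two_by_two(10, 10, 5, 15)
        res = logistic_adjusted(x, y)
        assert res.odds_ratio == pytest.approx((10 * 15) / (5 * 10), abs=1e-6)

    def test_constant_predictor_flagged(self):
        x = pd.Series(np.ones(20))
        y = pd.Series([1.0] * 10 + [0.0] * 10)
        res = logistic_adjusted(x, y)
        assert res.flagged and np.isinf(res.odds_ratio)

    def test_perfect_separation_flagged_not_crash(self):
        x = pd.Series(np.arange(10.0))
        y = pd.Series([0.0] * 5 + [1.0] * 5)
        res = logistic_adjusted(x, y)
        assert res.flagged

    def test_orthogonal_covariate_leaves_or_unchanged(self):
        # covariate balanced within every (predictor, outcome) cell: its
        # MLE coefficient is 0 and the marker OR is untouched
        x, y = self._two_by_two(10, 10, 6, 14)
        z = []
        for cell in [(1, 1)] * 10 + [(1, 0)] * 10 + [(0, 1)] * 6 + [(0, 0)] * 14:
            z.append(len(z) % 2)
        # rebuild z so it alternates within each cell
        z = pd.Series([i % 2 for i in range(10)] + [i % 2 for i in range(10)]
                      + [i % 2 for i in range(6)] + [i % 2 for i in range(14)], dtype=float)
        plain = logistic_adjusted(x, y)
        adj = logistic_adjusted(x, y, covariates=pd.DataFrame({"z": z}))
        assert adj.odds_ratio == pytest.approx(plain.odds_ratio, abs=1e-6)

    def test_missing_covariate_rejected(self):
        x, y = self._two_by_two(5, 5, 5, 5)
        cov = pd.DataFrame({"age": [60.0] * 19 + [np.nan]})
        with pytest.raises(ValueError, match="age"):
            logistic_adjusted(x, y, covariates=cov)


# ---------------------------------------------------------------------------
# group comparisons


class TestGroupCompare:
    def test_sex_table_chi_square(self):
        # male/female split 5/8 controls vs 7/6 cases
        res = group_compare([[5, 8], [7, 6]], kind="categorical")
        assert res["test_name"] == "chi2"
        assert res["p"] == pytest.approx(0.431, abs=5e-4)

    def test_smoking_table_uses_fisher(self):
        # expected counts < 5 force the exact test
        res = group_compare([[1, 12], [3, 10]], kind="categorical")
        assert res["test_name"] == "fisher_exact"
        assert res["p"] == pytest.approx(0.593, abs=5e-4)

    @given(st.tuples(*[st.integers(5, 30)] * 4))
    def test_chi2_closed_form(self, cells):
        a, b, c, d = cells
        res = group_compare([[a, b], [c, d]], kind="categorical")
        if res["test_name"] == "chi2":
            n = a + b + c + d
            expected = n * (a * d - b * c) ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
            assert res["statistic"] == pytest.approx(expected, rel=1e-10)

    def test_identical_continuous_samples(self):
        v = np.concatenate([np.arange(8.0), np.arange(8.0)])
        lab = np.array(["A"] * 8 + ["B"] * 8)
        res = group_compare(v, lab, kind="continuous")
        assert res["p"] == pytest.approx(1.0)
        assert res["statistic"] == pytest.approx(0.0)

    def test_skewed_data_routes_to_mannwhitney(self):
        rng = np.random.default_rng(9)
        a = np.exp(rng.normal(0, 2, 40))  # heavily lognormal
        b = np.exp(rng.normal(1, 2, 40))
        res = group_compare(np.concatenate([a, b]),
                            np.array(["A"] * 40 + ["B"] * 40), kind="continuous")
        assert res["test_name"] == "mannwhitney"

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            group_compare(np.arange(4.0), np.array(["A"] * 4), kind="continuous")
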