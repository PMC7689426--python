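import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cmrtexture.evaluate import (ClassifierSpec, CVResult,
                                 estimate_auc_correlation, hanley_mcneil,
                                 hanley_mcneil_se, mann_whitney, pooled_metrics,
                                 roc_auc, run_crossval)
from cmrtexture.naive_bayes_ref import GaussianNaiveBayes


def _toy_table(rng, n=40, n_pos=8, informative=False):
    y = np.zeros(n, dtype=int)
    y[:n_pos] = 1
    x = rng.normal(size=(n, 3))
    if informative:
        x[:n_pos, 0] += 5.0
    df = pd.DataFrame(x, columns=["f1", "f2", "f3"])
    df["MACCE"] = y
    return df


class TestCrossValidation:
    def test_separable_feature_gives_auc_one(self, rng):
        table = _toy_table(rng, informative=True)
        for name in ("NaiveBayes", "J48"):
            res = run_crossval(table, ClassifierSpec(name), k=5, seed=1)
            assert pooled_metrics(res)["roc_auc"] == pytest.approx(1.0)

    def test_null_labels_calibrate_to_half(self, rng):
        aucs = []
        for seed in range(20):
            table = _toy_table(rng)
            res = run_crossval(table, ClassifierSpec("NaiveBayes"), k=5, seed=seed)
            aucs.append(pooled_metrics(res)["roc_auc"])
        assert 0.40 <= np.mean(aucs) <= 0.60

    def test_folds_partition_cohort(self, rng):
        table = _toy_table(rng, n=23, n_pos=6)
        for seed in (0, 1, 2):
            res = run_crossval(table, ClassifierSpec("NaiveBayes"), k=5, seed=seed)
            counts = np.bincount(res.fold_of, minlength=5)
            assert counts.sum() == 23 and np.all(counts >= 1)

    def test_bit_reproducible_given_seed(self, rng):
        table = _toy_table(rng, informative=True)
        r1 = run_crossval(table, ClassifierSpec("RandomForest"), k=5, seed=9)
        r2 = run_crossval(table, ClassifierSpec("RandomForest"), k=5, seed=9)
        np.testing.assert_array_equal(r1.scores, r2.scores)
        np.testing.assert_array_equal(r1.y_pred, r2.y_pred)

    def test_more_folds_than_subjects_errors(self, rng):
        with pytest.raises(ValueError):
            run_crossval(_toy_table(rng, n=6, n_pos=2), ClassifierSpec("SMO"), k=10)

    def test_held_out_posteriors_match_reference_bayes(self, rng):
        # dual route: library-backed CV scores vs the from-scratch Gaussian
        # naive Bayes fitted per training fold (posteriors are invariant to
        # the per-fold affine standardization, so raw-space fits must agree)
        table = _toy_table(rng, n=12, n_pos=6, informative=True)
        res = run_crossval(table, ClassifierSpec("NaiveBayes"), k=2, seed=3)
        x = table.drop(columns="MACCE").to_numpy()
        y = table["MACCE"].to_numpy()
        for fold in (0, 1):
            te = res.fold_of == fold
            ref = GaussianNaiveBayes().fit(x[~te], y[~te])
            post = ref.predict_proba(x[te])[:, list(ref.classes_).index(1)]
            np.testing.assert_allclose(res.scores[te], post, atol=1e-6)

    def test_all_classifier_specs_build_and_run(self, rng):
        table = _toy_table(rng, informative=True)
        for name in ("ANN-MLP", "J48", "NaiveBayes", "RandomForest", "SMO"):
            res = run_crossval(table, ClassifierSpec(name), k=4, seed=0)
            assert len(res.scores) == len(table)


class TestReferenceNaiveBayes:
    def test_closed_form_posterior(self):
        # class 0: {0, 2} -> mu 1, var 1; class 1: {10, 14} -> mu 12, var 4
        x = np.array([[0.0], [2.0], [10.0], [14.0]])
        y = np.array([0, 0, 1, 1])
        model = GaussianNaiveBayes().fit(x, y)
        lik0 = math.exp(-(4 - 1) ** 2 / 2) / math.sqrt(2 * math.pi)
        lik1 = math.exp(-(4 - 12) ** 2 / (2 * 4)) / math.sqrt(2 * math.pi * 4)
        expected = lik1 / (lik0 + lik1)
        got = model.predict_proba([[4.0]])[0, 1]
        assert got == pytest.approx(expected, rel=1e-9)


class TestPooledMetrics:
    def _result(self, y, pred, scores):
        return CVResult(np.asarray(y), np.asarray(scores, dtype=float),
                        np.asarray(pred), np.zeros(len(y), dtype=int), 0,
                        ClassifierSpec("NaiveBayes"))

    def test_confusion_arithmetic(self, rng):
        y = np.array([1] * 6 + [0] * 52)
        pred = np.array([1] * 5 + [0] * 1 + [1] * 12 + [0] * 40)
        m = pooled_metrics(self._result(y, pred, rng.normal(size=58)))
        assert m["TP"] == 5 and m["FN"] == 1 and m["TN"] == 40 and m["FP"] == 12
        assert m["sensitivity"] == pytest.approx(5 / 6)
        assert m["specificity"] == pytest.approx(40 / 52)
        assert m["precision"] == pytest.approx(5 / 17)

    def test_orientation_exchange(self, rng):
        y = (rng.random(30) < 0.4).astype(int)
        pred = (rng.random(30) < 0.5).astype(int)
        scores = rng.normal(size=30)
        m1 = pooled_metrics(self._result(y, pred, scores), positive_class=1)
        m0 = pooled_metrics(self._result(y, pred, scores), positive_class=0)
        assert m1["sensitivity"] == pytest.approx(m0["specificity"])
        assert m1["specificity"] == pytest.approx(m0["sensitivity"])
        # scores are reoriented with the class, so discrimination is unchanged
        assert m1["roc_auc"] == pytest.approx(m0["roc_auc"])

    def test_auc_equals_scaled_mann_whitney_u(self, rng):
        y = np.array([1] * 10 + [0] * 15)
        scores = np.round(rng.normal(size=25), 1)   # force some ties
        auc = roc_auc(y, scores)
        u = mann_whitney(scores[y == 1], scores[y == 0]).u
        assert auc == pytest.approx(u / (10 * 15))

    def test_all_tied_scores_give_half(self):
        y = np.array([1, 1, 0, 0, 0])
        assert roc_auc(y, np.ones(5)) == 0.5

    def test_absent_positive_class_errors(self, rng):
        y = np.ones(10, dtype=int)
        with pytest.raises(ValueError, match="orientation"):
            pooled_metrics(self._result(y, y, rng.normal(size=10)),
                           positive_class=0)


class TestHanleyMcNeil:
    def test_perfect_auc_has_zero_se(self):
        assert hanley_mcneil_se(1.0, 6, 52) == 0.0

    def test_worked_standard_error(self):
        # A = 0.88, 6 events vs 52 non-events -> SE 0.0927 by the 1982 formula
        assert hanley_mcneil_se(0.88, 6, 52) == pytest.approx(0.0927, abs=5e-4)

    def test_equal_aucs_give_zero_z(self):
        cmp_ = hanley_mcneil(0.8, 6, 52, 0.8, r_hm=0.3)
        assert cmp_.z == 0.0 and cmp_.p == pytest.approx(1.0)

    def test_z_antisymmetric_under_swap(self):
        c12 = hanley_mcneil(0.88, 6, 52, 0.80, r_hm=0.4)
        c21 = hanley_mcneil(0.80, 6, 52, 0.88, r_hm=0.4)
        assert c12.z == pytest.approx(-c21.z)
        assert c12.p == pytest.approx(c21.p)

    def test_degenerate_comparison_errors(self):
        with pytest.raises(ValueError, match="undefined"):
            hanley_mcneil(1.0, 6, 52, 0.0, r_hm=1.0)   # both SEs exactly zero

    def test_score_correlation_estimate_bounds(self, rng):
        y = np.array([0] * 20 + [1] * 20)
        a = rng.normal(size=40)
        b = a + rng.normal(0, 0.3, 40)
        r = estimate_auc_correlation(a, b, y)
        assert 0.5 < r <= 1.0


class TestMannWhitney:
    def test_disjoint_groups_exact_enumeration(self):
        res = mann_whitney([1, 2, 3], [4, 5, 6])
        assert res.u == 0.0
        assert res.method == "exact"
        assert res.p == pytest.approx(0.1)    # 2 / C(6,3)

    def test_identical_groups_give_central_u(self):
        res = mann_whitney([1.0, 2.0, 5.0], [1.0, 2.0, 5.0])
        assert res.u == pytest.approx(4.5)    # n1 n2 / 2

    def test_all_equal_values_warn_p_one(self):
        with pytest.warns(UserWarning):
            res = mann_whitney([2, 2], [2, 2, 2])
        assert res.p == 1.0

    @given(st.lists(st.integers(0, 6), min_size=1, max_size=5),
           st.lists(st.integers(0, 6), min_size=1, max_size=5))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_u_complementarity(self, a, b):
        ua = mann_whitney(a, b).u
        ub = mann_whitney(b, a).u
        assert ua + ub == pytest.approx(len(a) * len(b))

    def test_normal_approximation_matches_scipy(self, rng):
        from scipy.stats import mannwhitneyu
        a = np.round(rng.normal(0.0, 1, 30), 1)
        b = np.round(rng.normal(0.4, 1, 25), 1)
        res = mann_whitney(a, b)
        assert res.method == "normal"
        ref = mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
        assert res.p == pytest.approx(ref.pvalue, rel=1e-9)

    def test_exact_p_matches_scipy_without_ties(self):
        from scipy.stats import mannwhitneyu
        a, b = [1.0, 4.0, 7.0], [2.0, 3.0, 9.0, 11.0]
        res = mann_whitney(a, b)
        ref = mannwhitneyu(a, b, alternative="two-sided", method="exact")
        assert res.p == pytest.approx(ref.pvalue, abs=1e-12)
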