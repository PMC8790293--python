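"""Stratified splits, the max-margin SVM, cross-validation and evaluation."""

import itertools

import numpy as np
import pytest

from pathmarker.classify import (
    cross_validate,
    decision_values,
    evaluate,
    predict,
    stratified_folds,
    stratified_split,
    train_svm,
)


class TestSplit:
    def test_published_cohort_split_counts(self):
        # 1104 tumor + 114 normal at 0.5 -> 552 + 57 = 609 per partition
        y = np.array([1] * 1104 + [-1] * 114)
        plan = stratified_split(y, 0.5, seed=3)
        for part in (plan.train, plan.test):
            part = np.array(part)
            assert part.size == 609
            assert int((y[part] == 1).sum()) == 552
            assert int((y[part] == -1).sum()) == 57

    def test_small_balanced_split(self):
        y = np.array([1, 1, 1, 1, -1, -1, -1, -1])
        for seed in range(5):
            plan = stratified_split(y, 0.5, seed=seed)
            assert int((y[list(plan.train)] == 1).sum()) == 2
            assert int((y[list(plan.train)] == -1).sum()) == 2

    def test_partition_properties_and_determinism(self):
        y = np.array([1] * 30 + [-1] * 11)
        a = stratified_split(y, 0.5, seed=9)
        b = stratified_split(y, 0.5, seed=9)
        c = stratified_split(y, 0.5, seed=10)
        assert a == b
        assert set(a.train) | set(a.test) == set(range(41))
        assert set(a.train) & set(a.test) == set()
        assert c.train != a.train  # different seed, different assignment
        assert len(c.train) == len(a.train)

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            stratified_split(np.array([1, 1, 1, -1]), 0.5, seed=0)


class TestSVM:
    def test_analytic_1d_toy(self):
        # negatives at 0, positives at 2: max margin gives w=1, b=-1
        X = np.array([[0.0], [0.0], [2.0], [2.0]])
        y = np.array([-1, -1, 1, 1])
        model = train_svm(X, y, C=1e6, standardize=False)
        assert model.w == pytest.approx([1.0], abs=1e-4)
        assert model.b == pytest.approx(-1.0, abs=1e-4)
        assert model.margin == pytest.approx(2.0, abs=1e-4)
        # arithmetic from the fitted model: x=3 scores 2
        assert decision_values(model, [[3.0]]) == pytest.approx([2.0], abs=1e-3)

    def test_hard_margin_constraints_on_separable_data(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(40, 3))
        y = np.where(X[:, 0] > 0, 1, -1)
        X[:, 0] += y * 1.0  # enforce a gap
        model = train_svm(X, y, C=1e6)
        Xs = (X - model.feature_mean) / model.feature_sd
        assert np.all(y * (Xs @ model.w + model.b) >= 1 - 1e-6)

    def test_margin_is_two_over_norm(self):
        rng = np.random.default_rng(4)
        X = rng.normal(size=(30, 2))
        y = np.where(X[:, 1] > 0, 1, -1)
        X[:, 1] += y * 2.0
        model = train_svm(X, y, C=1e6)
        assert model.margin == pytest.approx(2 / np.linalg.norm(model.w))

    def test_duplicating_training_points_changes_nothing(self):
        X = np.array([[0.0, 1.0], [1.0, 0.0], [2.0, 2.0], [3.0, 3.0]])
        y = np.array([-1, -1, 1, 1])
        m1 = train_svm(X, y, C=10.0, standardize=False)
        m2 = train_svm(np.vstack([X, X, X]), np.tile(y, 3), C=10.0,
                       standardize=False)
        assert m1.w == pytest.approx(m2.w, abs=1e-5)
        assert m1.b == pytest.approx(m2.b, abs=1e-5)

    def test_matches_reference_solver(self):
        # independent oracle: the same dual problem solved by scikit-learn
        sklearn_svm = pytest.importorskip("sklearn.svm")
        rng = np.random.default_rng(11)
        X = rng.normal(size=(60, 4))
        y = np.where(X[:, 0] + 0.5 * X[:, 1] > 0, 1, -1)
        for C in (0.5, 1.0, 10.0):
            ours = train_svm(X, y, C=C, standardize=False)
            ref = sklearn_svm.SVC(kernel="linear", C=C, tol=1e-8).fit(X, y)
            assert ours.w == pytest.approx(ref.coef_.ravel(), abs=1e-3)
            assert ours.b == pytest.approx(float(ref.intercept_[0]), abs=1e-3)

    def test_tie_at_zero_is_positive(self):
        X = np.array([[0.0], [2.0]])
        y = np.array([-1, 1])
        model = train_svm(X, y, C=1e6, standardize=False)
        assert predict(model, [[1.0]]) == [1]  # score 0 -> positive

    def test_nonfinite_features_rejected(self):
        with pytest.raises(ValueError):
            train_svm(np.array([[np.nan], [1.0]]), np.array([-1, 1]))

    def test_dimension_mismatch_rejected(self):
        model = train_svm(np.array([[0.0], [2.0]]), np.array([-1, 1]), C=1e6)
        with pytest.raises(ValueError):
            decision_values(model, np.zeros((3, 2)))


class TestEvaluate:
    def test_perfect_separation(self):
        rep = evaluate([1, 1, -1, -1], [2.0, 1.0, -1.0, -2.0])
        assert rep.auc == 1.0
        assert rep.sensitivity == 1.0 and rep.specificity == 1.0
        # a threshold achieving sens = spec = 1 exists on the ROC
        assert any(t == 1.0 and f == 0.0
                   for t, f in zip(rep.roc_tpr, rep.roc_fpr))

    def test_auc_matches_pair_counting_oracle(self):
        rng = np.random.default_rng(17)
        for _ in range(20):
            n = int(rng.integers(4, 12))
            y = rng.choice([1, -1], size=n)
            if len(set(y)) < 2:
                continue
            s = rng.integers(0, 4, size=n).astype(float)  # many ties
            pos = s[y == 1]
            neg = s[y == -1]
            pairs = [
                1.0 if a > b else (0.5 if a == b else 0.0)
                for a, b in itertools.product(pos, neg)
            ]
            assert evaluate(y, s).auc == pytest.approx(np.mean(pairs), abs=1e-12)

    def test_confusion_identities(self):
        rng = np.random.default_rng(19)
        y = rng.choice([1, -1], size=50)
        y[:2] = [1, -1]
        s = rng.normal(size=50)
        rep = evaluate(y, s)
        assert rep.tp + rep.fn == int((y == 1).sum())
        assert rep.tn + rep.fp == int((y == -1).sum())
        assert rep.accuracy == (rep.tp + rep.tn) / 50
        assert 0.0 <= rep.auc <= 1.0

    def test_published_confusion_arithmetic(self):
        # sensitivity 0.991 on 552 tumors and specificity 0.93 on 57 normals
        # imply 547 + 53 = 600 of 609 correct
        tp = round(0.991 * 552)
        tn = round(0.93 * 57)
        assert tp == 547 and tn == 53
        assert tp + tn == 600
        assert tp + tn <= 609

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            evaluate([1, 1], [0.1, 0.2])


class TestCrossValidate:
    def test_every_sample_in_exactly_one_test_fold(self):
        y = np.array([1] * 25 + [-1] * 15)
        folds = stratified_folds(y, 5, seed=1)
        all_idx = np.concatenate(folds)
        assert sorted(all_idx) == list(range(40))

    def test_well_separated_gaussians(self):
        rng = np.random.default_rng(23)
        X = rng.normal(size=(120, 4))
        y = np.array([1] * 60 + [-1] * 60)
        X[y == 1] += 6.0  # 6 sigma between class means
        rep = cross_validate(X, y, k=10, seed=0)
        assert rep.accuracy >= 0.99
        assert rep.auc >= 0.99

    def test_permuted_labels_null_auc(self):
        rng = np.random.default_rng(29)
        X = rng.normal(size=(200, 8))
        y = rng.permutation(np.array([1] * 100 + [-1] * 100))
        rep = cross_validate(X, y, k=10, seed=0)
        assert abs(rep.auc - 0.5) <= 0.07

    def test_k_reduced_with_warning_for_small_class(self):
        rng = np.random.default_rng(31)
        X = rng.normal(size=(24, 2))
        y = np.array([1] * 20 + [-1] * 4)
        with pytest.warns(UserWarning, match="reducing k"):
            cross_validate(X, y, k=10, seed=0)

    def test_k_below_two_rejected(self):
        with pytest.raises(ValueError):
            cross_validate(np.zeros((4, 1)), np.array([1, 1, -1, -1]), k=1)
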