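"""SVM/NB training, cross-validation, metrics arithmetic and ROC/AUC."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tonguethermo import (
    ConfusionMatrix,
    CVConfig,
    crossvalidate,
    fit_nb_gaussian,
    fit_svm_linear,
    metrics_from_confusion,
    roc_auc,
)
from tonguethermo.classify import NEGATIVE, POSITIVE


def _blobs(n_per_class, separation, dim=4, seed=0):
    rng = np.random.default_rng(seed)
    a = rng.standard_normal((n_per_class, dim)) - separation / 2
    b = rng.standard_normal((n_per_class, dim)) + separation / 2
    X = np.vstack([a, b])
    y = np.array([NEGATIVE] * n_per_class + [POSITIVE] * n_per_class)
    return X, y


class TestSVM:
    def test_two_point_toy_classified_correctly(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        y = np.array([NEGATIVE, POSITIVE])
        model = fit_svm_linear(X, y)
        assert list(model.predict(X)) == [NEGATIVE, POSITIVE]
        # the margin midpoint lies on x + y = 1
        assert model.decision_function([[0.5, 0.5]])[0] == pytest.approx(0.0, abs=1e-6)

    def test_xor_not_linearly_separable(self):
        X = np.array([[0, 0], [0, 1], [1, 0], [1, 1]], dtype=float)
        y = np.array([NEGATIVE, POSITIVE, POSITIVE, NEGATIVE])
        model = fit_svm_linear(X, y)
        assert np.mean(model.predict(X) == y) <= 0.75

    def test_label_flip_negates_decision_function(self):
        X, y = _blobs(20, 3.0, seed=1)
        up = fit_svm_linear(X, y)
        down = fit_svm_linear(X, -y)
        # symmetry holds up to the solver's convergence tolerance
        assert np.allclose(up.decision_function(X),
                           -down.decision_function(X), atol=1e-2)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            fit_svm_linear(np.zeros((5, 2)), np.ones(5))


class TestNaiveBayes:
    def test_symmetric_classes_give_boundary_at_zero(self):
        rng = np.random.default_rng(3)
        X = np.concatenate([rng.normal(-1, 1, 500), rng.normal(1, 1, 500)])[:, None]
        y = np.array([NEGATIVE] * 500 + [POSITIVE] * 500)
        model = fit_nb_gaussian(X, y)
        assert model.predict([[-0.5]])[0] == NEGATIVE
        assert model.predict([[0.5]])[0] == POSITIVE

    def test_constant_feature_posterior_equals_priors(self):
        X = np.ones((10, 1))
        y = np.array([POSITIVE] * 7 + [NEGATIVE] * 3)
        model = fit_nb_gaussian(X, y)
        proba = model.predict_proba([[1.0]])[0]
        classes = list(model.classes_)
        assert proba[classes.index(POSITIVE)] == pytest.approx(0.7, abs=1e-6)

    def test_prior_shift_moves_boundary_toward_rare_class(self):
        rng = np.random.default_rng(4)
        X = np.concatenate([rng.normal(-1, 1, 900), rng.normal(1, 1, 100)])[:, None]
        y = np.array([NEGATIVE] * 900 + [POSITIVE] * 100)
        model = fit_nb_gaussian(X, y)
        # equal-likelihood point x=0 now classifies as the common class
        assert model.predict([[0.0]])[0] == NEGATIVE
        assert model.predict([[2.5]])[0] == POSITIVE


class TestMetrics:
    @pytest.mark.parametrize(
        "counts, expected",
        [
            # (TP, FP, TN, FN) -> published screening-table rows
            ((63, 3, 67, 7), {"sensitivity": 90.00, "specificity": 95.71,
                              "accuracy": 92.85, "npv": 90.54, "ppv": 95.45}),
            ((67, 12, 58, 3), {"sensitivity": 95.71, "specificity": 82.85,
                               "accuracy": 89.28, "ppv": 84.81, "npv": 95.08}),
            ((65, 3, 67, 5), {"sensitivity": 92.85, "specificity": 95.71,
                              "accuracy": 94.28, "ppv": 95.58, "npv": 93.05}),
            ((70, 0, 70, 0), {"sensitivity": 100.0, "specificity": 100.0,
                              "accuracy": 100.0, "ppv": 100.0, "npv": 100.0}),
        ],
    )
    def test_metric_arithmetic(self, counts, expected):
        m = metrics_from_confusion(ConfusionMatrix(*counts))
        for name, want in expected.items():
            assert getattr(m, name) == pytest.approx(want, abs=1e-9)

    def test_truncation_not_rounding(self):
        # 130/140 = 92.857...% -> 92.85 truncated (92.86 if rounded)
        m = metrics_from_confusion(ConfusionMatrix(63, 3, 67, 7))
        assert m.accuracy == 92.85
        m2 = metrics_from_confusion(ConfusionMatrix(63, 3, 67, 7), rounding="round")
        assert m2.accuracy == 92.86

    def test_zero_denominator_flagged(self):
        m = metrics_from_confusion(ConfusionMatrix(0, 0, 5, 0))
        assert np.isnan(m.sensitivity) and np.isnan(m.ppv)
        assert m.undefined == {"sensitivity", "ppv"}
        assert m.specificity == 100.0

    @settings(deadline=None, derandomize=True, max_examples=60)
    @given(st.tuples(st.integers(1, 200), st.integers(1, 200),
                     st.integers(1, 200), st.integers(1, 200)))
    def test_accuracy_identity(self, counts):
        """accuracy = (sens*(TP+FN) + spec*(TN+FP)) / total, exactly."""
        tp, fp, tn, fn = counts
        m = metrics_from_confusion(ConfusionMatrix(tp, fp, tn, fn),
                                   rounding="none")
        total = tp + fp + tn + fn
        want = (m.sensitivity * (tp + fn) + m.specificity * (tn + fp)) / total
        assert m.accuracy == pytest.approx(want, abs=1e-9)


class TestROC:
    def test_perfectly_ranked_scores(self):
        labels = np.array([NEGATIVE] * 5 + [POSITIVE] * 5)
        _, _, auc = roc_auc(np.arange(10.0), labels)
        assert auc == 1.0
        _, _, auc_rev = roc_auc(-np.arange(10.0), labels)
        assert auc_rev == 0.0

    def test_random_scores_near_half(self):
        rng = np.random.default_rng(6)
        labels = np.where(rng.random(1000) < 0.5, POSITIVE, NEGATIVE)
        _, _, auc = roc_auc(rng.standard_normal(1000), labels)
        assert auc == pytest.approx(0.5, abs=0.05)

    def test_equals_mann_whitney_oracle_with_ties(self, rng):
        """Trapezoidal AUC = pairwise comparison count (ties half)."""
        for _ in range(20):
            scores = rng.integers(0, 6, size=40).astype(float)  # heavy ties
            labels = np.where(rng.random(40) < 0.5, POSITIVE, NEGATIVE)
            if len(np.unique(labels)) < 2:
                continue
            _, _, auc = roc_auc(scores, labels)
            pos = scores[labels == POSITIVE]
            neg = scores[labels == NEGATIVE]
            wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
            assert auc == pytest.approx(wins / (len(pos) * len(neg)), abs=1e-12)

    def test_matches_sklearn(self, rng):
        from sklearn.metrics import roc_auc_score

        scores = rng.standard_normal(200)
        labels = np.where(rng.random(200) < 0.4, POSITIVE, NEGATIVE)
        _, _, auc = roc_auc(scores, labels)
        assert auc == pytest.approx(roc_auc_score(labels == POSITIVE, scores))

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc(np.arange(4.0), np.full(4, POSITIVE))


class TestCrossValidation:
    def test_separable_data_perfect_pooled_confusion(self):
        X, y = _blobs(30, 10.0, seed=7)
        res = crossvalidate("svm", X, y, CVConfig(k=5, seed=0))
        assert res.confusion.fp == 0 and res.confusion.fn == 0

    def test_same_seed_reproduces_folds(self):
        X, y = _blobs(25, 1.0, seed=8)
        r1 = crossvalidate("svm", X, y, CVConfig(k=5, seed=3))
        r2 = crossvalidate("svm", X, y, CVConfig(k=5, seed=3))
        assert r1.confusion == r2.confusion
        assert np.array_equal(r1.scores, r2.scores)

    def test_k_larger_than_minority_rejected(self):
        X, y = _blobs(4, 1.0)
        with pytest.raises(ValueError):
            crossvalidate("svm", X, y, CVConfig(k=10))

    @pytest.mark.parametrize("model", ["svm", "nb"])
    def test_random_labels_give_chance_accuracy(self, model):
        accs = []
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            X = rng.standard_normal((60, 5))
            y = np.array([NEGATIVE] * 30 + [POSITIVE] * 30)
            res = crossvalidate(model, X, y, CVConfig(k=5, seed=seed))
            accs.append(res.pooled_accuracy)
        assert np.mean(accs) == pytest.approx(0.5, abs=0.1)

    @pytest.mark.parametrize("model", ["svm", "nb"])
    def test_no_leakage_informative_features_shuffled_labels(self, model):
        """Shuffling labels kills accuracy even with structured features."""
        X, y = _blobs(30, 5.0, seed=9)
        rng = np.random.default_rng(10)
        accs = []
        for seed in range(10):
            y_shuf = rng.permutation(y)
            res = crossvalidate(model, X, y_shuf, CVConfig(k=5, seed=seed))
            accs.append(res.pooled_accuracy)
        assert np.mean(accs) < 0.65
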