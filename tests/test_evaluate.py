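"""Evaluation metrics against brute-force oracles, Bayesian-optimized SVM,
and cross-validation fold semantics."""

import numpy as np
import pytest
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.model_selection import cross_val_score
from sklearn.svm import SVC

from gaitndd.evaluate import (
    BayesSVC,
    CVScheme,
    MetricUndefinedError,
    compute_metrics,
    cross_validate,
    make_folds,
    multiclass_evaluate,
    select_best_config,
    train_svm,
    youden_index,
)


def auc_pair_oracle(y, scores, positive=1):
    """Brute force over all positive x negative pairs; ties count 1/2."""
    pos = scores[y == positive]
    neg = scores[y != positive]
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


def youden_sweep_oracle(y, scores, positive=1):
    """Exhaustive sweep over every distinct score as a candidate cutpoint."""
    best = -2
    for c in np.concatenate([np.unique(scores), [np.inf, -np.inf]]):
        pred = scores >= c
        sens = (pred & (y == positive)).sum() / (y == positive).sum()
        spec = (~pred & (y != positive)).sum() / (y != positive).sum()
        best = max(best, sens + spec - 1)
    return best


class ScoreColumnClassifier(BaseEstimator, ClassifierMixin):
    """Thresholds the first feature column; the 'perfect features' stub."""

    def fit(self, X, y):
        self.classes_ = np.unique(y)
        return self

    def predict(self, X):
        return np.where(X[:, 0] >= 0.5, self.classes_[1], self.classes_[0])

    def decision_function(self, X):
        return X[:, 0] - 0.5


class TestComputeMetrics:
    def test_formula_substitution(self):
        y = np.array([1] * 10 + [0] * 10)
        pred = np.array([1] * 9 + [0] + [1] * 2 + [0] * 8)
        scores = np.where(pred == 1, 1.0, -1.0) + np.linspace(0, 0.1, 20)
        rep = compute_metrics(y, scores, 1, y_pred=pred)
        assert rep.sensitivity == pytest.approx(90.0)
        assert rep.specificity == pytest.approx(80.0)
        assert rep.accuracy == pytest.approx(85.0)
        assert rep.confusion.sum() == 20

    def test_tied_scores_auc_half(self):
        y = np.array([0, 0, 1, 1])
        rep = compute_metrics(y, np.zeros(4), 1, y_pred=np.array([0, 0, 1, 1]))
        assert rep.auc == pytest.approx(0.5)

    def test_auc_matches_pair_oracle(self, rng):
        y = rng.integers(0, 2, 500)
        scores = rng.standard_normal(500)
        rep = compute_metrics(y, scores, 1)
        assert rep.auc == pytest.approx(auc_pair_oracle(y, scores), abs=1e-12)

    def test_one_class_absent_flagged(self):
        with pytest.raises(MetricUndefinedError):
            compute_metrics(np.ones(5), np.arange(5.0), 1)

    def test_accuracy_identity_binary(self, rng):
        y = rng.integers(0, 2, 200)
        scores = rng.standard_normal(200) + y
        rep = compute_metrics(y, scores, 1)
        p, n = (y == 1).sum(), (y == 0).sum()
        assert rep.accuracy == pytest.approx(
            (rep.sensitivity * p + rep.specificity * n) / (p + n)
        )


class TestYouden:
    def test_perfect_separation(self):
        y = np.array([0, 0, 0, 1, 1, 1])
        j, c = youden_index(y, np.array([0.1, 0.2, 0.3, 0.7, 0.8, 0.9]), 1)
        assert j == pytest.approx(1.0)
        assert 0.3 < c < 0.7

    def test_identical_distributions_near_zero(self, rng):
        y = np.array([0, 1] * 250)
        scores = rng.standard_normal(500)
        j, _ = youden_index(y, scores, 1)
        assert 0 <= j < 0.2

    def test_matches_exhaustive_sweep(self):
        y = np.array([1, 1, 1, 0, 0, 0])
        scores = np.array([0.9, 0.8, 0.4, 0.7, 0.3, 0.2])
        j, c = youden_index(y, scores, 1)
        assert j == pytest.approx(youden_sweep_oracle(y, scores))
        # identity at the selected cutpoint
        pred = scores >= c
        sens = (pred & (y == 1)).sum() / 3
        spec = (~pred & (y == 0)).sum() / 3
        assert j == pytest.approx(sens + spec - 1, abs=1e-12)

    def test_random_cases_match_sweep_oracle(self, rng):
        for _ in range(20):
            y = rng.integers(0, 2, 30)
            if y.min() == y.max():
                continue
            scores = rng.choice([0.1, 0.2, 0.5, 0.7], size=30)
            j, _ = youden_index(y, scores, 1)
            assert j == pytest.approx(youden_sweep_oracle(y, scores), abs=1e-12)

    def test_identity_in_report(self, rng):
        y = rng.integers(0, 2, 100)
        scores = rng.standard_normal(100) + 0.5 * y
        rep = compute_metrics(y, scores, 1)
        assert rep.youden_j == pytest.approx(
            rep.youden_sensitivity / 100 + rep.youden_specificity / 100 - 1, abs=1e-12
        )


class TestSelectBestConfig:
    @staticmethod
    def _report(j, acc=90.0, auc=0.9):
        rep = compute_metrics(
            np.array([0, 1]), np.array([-1.0, 1.0]), 1, y_pred=np.array([0, 1])
        )
        rep.youden_j, rep.accuracy, rep.auc = j, acc, auc
        return rep

    def test_orders_by_j(self):
        ranked = select_best_config([self._report(0.9), self._report(0.95)])
        assert ranked[0].youden_j == 0.95

    def test_tie_broken_by_accuracy(self):
        ranked = select_best_config([self._report(0.9, 96), self._report(0.9, 98)])
        assert ranked[0].accuracy == 98

    def test_single_report_unchanged(self):
        rep = self._report(0.5)
        assert select_best_config([rep]) == [rep]


class TestBayesSVC:
    def test_separable_blobs_training_accuracy(self, rng):
        X = np.concatenate([rng.normal(-2, 0.3, (30, 2)), rng.normal(2, 0.3, (30, 2))])
        y = np.array([0] * 30 + [1] * 30)
        clf = train_svm(X, y, bayes_iters=12, seed=0)
        assert (clf.predict(X) == y).mean() == 1.0

    def test_seeded_determinism(self, rng):
        X = rng.standard_normal((40, 3))
        y = (X[:, 0] > 0).astype(int)
        a = BayesSVC(n_iter=10, random_state=1).fit(X, y)
        b = BayesSVC(n_iter=10, random_state=1).fit(X, y)
        assert a.best_params_ == b.best_params_

    def test_beats_linear_kernel_on_xor(self, rng):
        n = 200
        X = rng.uniform(-1, 1, (n, 2))
        y = ((X[:, 0] > 0) ^ (X[:, 1] > 0)).astype(int)
        clf = BayesSVC(n_iter=20, random_state=0).fit(X, y)
        best_linear = max(
            cross_val_score(SVC(kernel="linear", C=c), X, y, cv=5).mean()
            for c in [0.01, 0.1, 1, 10, 100]
        )
        assert clf.best_score_ > best_linear

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            BayesSVC(n_iter=2).fit(np.ones((5, 2)), np.ones(5))


class TestFolds:
    def test_loocv_unit_counts(self):
        y = np.array(["a", "b"] * 5)
        units = np.arange(10)
        folds = make_folds(y, units, CVScheme(kind="loocv", unit="window"))
        assert len(folds) == 10
        assert all(len(te) == 1 for _tr, te in folds)

    def test_subject_mode_never_splits_subject(self):
        y = np.repeat(["a", "b"], 30)
        units = np.repeat(np.arange(12), 5)
        folds = make_folds(y, units, CVScheme(kind="kfold", k=5, unit="subject", seed=0))
        for _tr, te in folds:
            for u in np.unique(units[te]):
                assert set(np.nonzero(units == u)[0]) <= set(te)

    def test_every_unit_tested_exactly_once(self):
        y = np.repeat(["a", "b"], 25)
        units = np.repeat(np.arange(10), 5)
        folds = make_folds(y, units, CVScheme(kind="kfold", k=5, unit="subject", seed=1))
        tested = np.concatenate([te for _tr, te in folds])
        assert sorted(tested) == list(range(50))

    def test_too_few_units_per_class_rejected(self):
        y = np.repeat(["a", "b"], 3)
        with pytest.raises(ValueError):
            make_folds(y, np.arange(6), CVScheme(kind="kfold", k=5, unit="window"))


class TestCrossValidate:
    def test_perfect_features_any_scheme(self, rng):
        y = np.array(["HC", "ALS"] * 20)
        # sklearn convention: decision > 0 predicts classes_[1] ("HC" here)
        X = np.column_stack([(y == "HC").astype(float), rng.standard_normal(40)])
        for scheme in (CVScheme("loocv", unit="window"),
                       CVScheme("kfold", k=5, unit="window", seed=0)):
            rep = cross_validate(X, y, np.arange(40), scheme, ScoreColumnClassifier())
            assert rep.accuracy == 100.0
            assert rep.auc == 1.0
            assert rep.youden_j == 1.0

    def test_loocv_round_count(self, rng):
        y = np.array(["HC", "ALS"] * 5)
        X = rng.standard_normal((10, 2))
        rep = cross_validate(
            X, y, np.arange(10), CVScheme("loocv", unit="window"),
            ScoreColumnClassifier(),
        )
        assert rep.meta["n_folds"] == 10

    def test_shuffled_labels_near_chance(self):
        rng = np.random.default_rng(2024)
        n = 200
        X = rng.standard_normal((n, 3))
        y = np.array(["HC"] * 100 + ["ALS"] * 100)
        rng.shuffle(y)
        rep = cross_validate(
            X, y, np.arange(n), CVScheme("kfold", k=5, unit="window", seed=0),
            lambda: SVC(kernel="rbf"),
        )
        assert 40.0 <= rep.accuracy <= 60.0
        assert 0.4 <= rep.auc <= 0.6

    def test_missing_class_in_training_fold_reported(self):
        y = np.array(["HC"] * 9 + ["ALS"])
        X = np.random.default_rng(0).standard_normal((10, 2))
        with pytest.raises(ValueError, match="ALS"):
            cross_validate(
                X, y, np.arange(10), CVScheme("loocv", unit="window"),
                ScoreColumnClassifier(),
            )


class TestMulticlass:
    @staticmethod
    def _four_class_data(rng, confuse=False):
        centers = {"HC": (0, 0), "ALS": (6, 0), "HD": (0, 6), "PD": (6, 6)}
        X, y, units = [], [], []
        for gi, (g, c) in enumerate(centers.items()):
            for u in range(6):
                pts = rng.normal(c, 0.4, (4, 2))
                if confuse and g == "PD":
                    pts = rng.normal(centers["HD"], 0.4, (4, 2))
                X.append(pts)
                y += [g] * 4
                units += [f"{g}{u}"] * 4
        return np.concatenate(X), np.array(y), np.array(units)

    def test_separated_classes_full_sensitivity(self, rng):
        X, y, units = self._four_class_data(rng)
        rep = multiclass_evaluate(
            X, y, units, CVScheme("kfold", k=5, unit="subject", seed=0),
            lambda: SVC(kernel="rbf", C=10, decision_function_shape="ovr"),
        )
        for cls, sub in rep.per_class.items():
            assert sub.sensitivity == 100.0
        assert rep.confusion.sum(axis=1).tolist() == [24, 24, 24, 24]

    def test_confused_pair_degrades_together(self, rng):
        X, y, units = self._four_class_data(rng, confuse=True)
        rep = multiclass_evaluate(
            X, y, units, CVScheme("kfold", k=5, unit="subject", seed=0),
            lambda: SVC(kernel="rbf", C=10, decision_function_shape="ovr"),
        )
        degraded = min(rep.per_class["HD"].sensitivity, rep.per_class["PD"].sensitivity)
        assert degraded < 100.0
        assert rep.per_class["HC"].sensitivity == 100.0
        assert rep.per_class["ALS"].sensitivity == 100.0
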