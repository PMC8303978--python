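"""SVM classification and evaluation: cross-validation, ROC metrics, Youden J.

Binary screening tasks report sensitivity / specificity / accuracy (as
percentages, from pooled cross-validated predictions), AUC (from pooled
decision scores), and Youden's index

    J = max_c { sensitivity(c) + specificity(c) - 1 },

the maximum over all score cutpoints c, which is also the criterion used
to pick the best configuration among transforms / windows / schemes.
The report carries two operating points: the classifier's own prediction
threshold (confusion, sensitivity, specificity, accuracy) and the
Youden-optimal cutpoint (youden_j, youden_cutpoint and the sensitivity /
specificity attained there, which satisfy the J identity exactly).

The SVM is an RBF-kernel SVC whose box constraint C and kernel scale
gamma are chosen by Bayesian optimization (Gaussian-process surrogate,
expected-improvement acquisition, 30 evaluations) scored by inner
stratified 5-fold accuracy on the training set only.

Cross-validation supports leave-one-out and stratified 5-fold at either
window or subject granularity; subject mode keeps all windows of one
subject in a single fold (no identity leakage).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy.stats import norm
from sklearn.base import BaseEstimator, ClassifierMixin, clone
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.gaussian_process.kernels import ConstantKernel, Matern, WhiteKernel
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC


class MetricUndefinedError(ValueError):
    """A requested metric is undefined (e.g. one class absent)."""


# --------------------------------------------------------------------------
# metrics


def youden_index(
    y_true: np.ndarray, scores: np.ndarray, positive_label=1
) -> tuple[float, float]:
    """Maximize sensitivity(c) + specificity(c) - 1 over all cutpoints.

    Candidate cutpoints are the midpoints between consecutive sorted
    distinct scores plus -inf / +inf sentinels (this finite sweep attains
    the supremum over all real c).  Returns (J, cutpoint); a sample is
    called positive when its score >= cutpoint.
    """
    j, c, _, _ = _youden_sweep(y_true, scores, positive_label)
    return j, c


def _youden_sweep(y_true, scores, positive_label):
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == positive_label
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise MetricUndefinedError("both classes must be present")
    distinct = np.unique(scores)
    cuts = np.concatenate(
        [[-np.inf], (distinct[:-1] + distinct[1:]) / 2.0, [np.inf]]
    )
    best = (-2.0, 0.0, 0.0, 0.0)
    for c in cuts:
        pred = scores >= c
        sens = (pred & pos).sum() / n_pos
        spec = (~pred & ~pos).sum() / n_neg
        j = sens + spec - 1.0
        if j > best[0]:
            best = (float(j), float(c), float(sens), float(spec))
    return best


def auc_score(y_true, scores, positive_label=1) -> float:
    """ROC AUC of real-valued scores (rank statistic; ties count 1/2)."""
    y_true = np.asarray(y_true)
    pos = y_true == positive_label
    if pos.all() or not pos.any():
        raise MetricUndefinedError("both classes must be present for AUC")
    return float(roc_auc_score(pos.astype(int), scores))


@dataclass
class EvalReport:
    """Pooled cross-validated evaluation of one classification task."""

    task: str
    classes: tuple
    confusion: np.ndarray  # rows = true class, cols = predicted
    sensitivity: float  # percent, at the classifier's prediction threshold
    specificity: float  # percent
    accuracy: float  # percent
    auc: float  # fraction in [0, 1]
    youden_j: float
    youden_cutpoint: float = float("nan")
    youden_sensitivity: float = float("nan")  # percent, at the Youden cutpoint
    youden_specificity: float = float("nan")  # percent
    n_test: int = 0
    per_class: dict = field(default_factory=dict)
    meta: dict = field(default_factory=dict)


def compute_metrics(
    y_true: np.ndarray,
    scores: np.ndarray,
    positive_label,
    y_pred: np.ndarray | None = None,
    task: str = "",
) -> EvalReport:
    """Binary EvalReport from pooled labels, scores, and predictions.

    ``scores`` are decision values oriented so larger means more likely
    positive.  When ``y_pred`` is omitted, the prediction threshold is
    score >= 0.
    """
    y_true = np.asarray(y_true)
    scores = np.asarray(scores, dtype=float)
    pos = y_true == positive_label
    if y_pred is None:
        pred_pos = scores >= 0
    else:
        pred_pos = np.asarray(y_pred) == positive_label
    tp = int((pred_pos & pos).sum())
    fn = int((~pred_pos & pos).sum())
    tn = int((~pred_pos & ~pos).sum())
    fp = int((pred_pos & ~pos).sum())
    if tp + fn == 0 or tn + fp == 0:
        raise MetricUndefinedError(
            "sensitivity or specificity undefined: one class absent"
        )
    sens = 100.0 * tp / (tp + fn)
    spec = 100.0 * tn / (tn + fp)
    acc = 100.0 * (tp + tn) / len(y_true)
    auc = auc_score(y_true, scores, positive_label)
    j, c, jsens, jspec = _youden_sweep(y_true, scores, positive_label)
    neg_label = [cl for cl in np.unique(y_true) if cl != positive_label]
    neg_name = neg_label[0] if len(neg_label) == 1 else "rest"
    return EvalReport(
        task=task or f"{positive_label} vs {neg_name}",
        classes=(neg_name, positive_label),
        confusion=np.array([[tn, fp], [fn, tp]]),
        sensitivity=sens,
        specificity=spec,
        accuracy=acc,
        auc=auc,
        youden_j=j,
        youden_cutpoint=c,
        youden_sensitivity=100.0 * jsens,
        youden_specificity=100.0 * jspec,
        n_test=len(y_true),
    )


def select_best_config(reports: Sequence[EvalReport]) -> list[EvalReport]:
    """Rank reports by Youden J, ties broken by accuracy then AUC."""
    if not reports:
        raise ValueError("need at least one report")
    return sorted(
        reports, key=lambda r: (r.youden_j, r.accuracy, r.auc), reverse=True
    )


# --------------------------------------------------------------------------
# Bayesian-optimized SVM


class BayesSVC(BaseEstimator, ClassifierMixin):
    """RBF-kernel SVC with GP expected-improvement hyperparameter search.

    The search space is log-uniform: C in [1e-3, 1e3], gamma in [1e-4, 10].
    ``n_iter`` total objective evaluations (default 30): ``n_init`` seeded
    quasi-random points, then expected-improvement steps with a Matern-5/2
    Gaussian-process surrogate over (log10 C, log10 gamma).  The objective
    is mean stratified ``inner_cv``-fold accuracy on the training data
    only.  Fully deterministic given ``random_state``.
    """

    def __init__(
        self,
        n_iter: int = 30,
        n_init: int = 8,
        C_bounds: tuple[float, float] = (1e-3, 1e3),
        gamma_bounds: tuple[float, float] = (1e-4, 10.0),
        inner_cv: int = 5,
        random_state: int = 0,
    ):
        self.n_iter = n_iter
        self.n_init = n_init
        self.C_bounds = C_bounds
        self.gamma_bounds = gamma_bounds
        self.inner_cv = inner_cv
        self.random_state = random_state

    def _objective(self, X, y, log_c, log_g) -> float:
        counts = np.unique(y, return_counts=True)[1]
        k = int(min(self.inner_cv, counts.min()))
        if k < 2:
            raise ValueError("every class needs >= 2 training samples")
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=self.random_state)
        accs = []
        for tr, te in skf.split(X, y):
            svc = SVC(kernel="rbf", C=10.0**log_c, gamma=10.0**log_g)
            svc.fit(X[tr], y[tr])
            accs.append(np.mean(svc.predict(X[te]) == y[te]))
        return float(np.mean(accs))

    def fit(self, X: np.ndarray, y: np.ndarray) -> "BayesSVC":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least 2 classes")
        if self.n_iter < 1:
            raise ValueError("n_iter must be >= 1")
        rng = np.random.default_rng(self.random_state)
        lo = np.log10([self.C_bounds[0], self.gamma_bounds[0]])
        hi = np.log10([self.C_bounds[1], self.gamma_bounds[1]])
        pts: list[np.ndarray] = []
        vals: list[float] = []
        n_init = min(self.n_init, self.n_iter)
        for _ in range(n_init):
            p = lo + rng.random(2) * (hi - lo)
            pts.append(p)
            vals.append(self._objective(X, y, *p))
        # fixed surrogate hyperparameters: length scales in log10-parameter
        # units; keeps the search fast and fully deterministic
        kernel = ConstantKernel(0.1, constant_value_bounds="fixed") * Matern(
            length_scale=[2.0, 2.0], length_scale_bounds="fixed", nu=2.5
        ) + WhiteKernel(noise_level=1e-4, noise_level_bounds="fixed")
        for _ in range(self.n_iter - n_init):
            gp = GaussianProcessRegressor(
                kernel=kernel, normalize_y=True, random_state=self.random_state
            )
            gp.fit(np.array(pts), np.array(vals))
            cand = lo + rng.random((256, 2)) * (hi - lo)
            mu, sigma = gp.predict(cand, return_std=True)
            best = max(vals)
            sigma = np.maximum(sigma, 1e-12)
            z = (mu - best) / sigma
            ei = (mu - best) * norm.cdf(z) + sigma * norm.pdf(z)
            p = cand[int(np.argmax(ei))]
            pts.append(p)
            vals.append(self._objective(X, y, *p))
        ibest = int(np.argmax(vals))
        log_c, log_g = pts[ibest]
        self.best_params_ = {"C": 10.0**log_c, "gamma": 10.0**log_g}
        self.best_score_ = vals[ibest]
        self.search_points_ = np.array(pts)
        self.search_values_ = np.array(vals)
        self.svc_ = SVC(
            kernel="rbf", decision_function_shape="ovr", **self.best_params_
        )
        self.svc_.fit(X, y)
        return self

    def predict(self, X: np.ndarray) -> np.ndarray:
        return self.svc_.predict(np.asarray(X, dtype=float))

    def decision_function(self, X: np.ndarray) -> np.ndarray:
        return self.svc_.decision_function(np.asarray(X, dtype=float))


def train_svm(
    features: np.ndarray, labels: np.ndarray, bayes_iters: int = 30, seed: int = 0
) -> BayesSVC:
    """Fit a Bayesian-optimized RBF SVM on a feature matrix."""
    return BayesSVC(n_iter=bayes_iters, random_state=seed).fit(features, labels)


# --------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class CVScheme:
    """Cross-validation plan: LOOCV or stratified k-fold, by window or subject."""

    kind: str = "kfold"  # "loocv" or "kfold"
    k: int = 5
    unit: str = "subject"  # "window" or "subject"
    seed: int = 0
    stratified: bool = True

    def __post_init__(self):
        if self.kind not in ("loocv", "kfold"):
            raise ValueError("kind must be 'loocv' or 'kfold'")
        if self.unit not in ("window", "subject"):
            raise ValueError("unit must be 'window' or 'subject'")


def make_folds(
    y: np.ndarray, units: np.ndarray, scheme: CVScheme
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(train_idx, test_idx) pairs; every unit is tested exactly once and
    all samples of one unit share a fold."""
    y = np.asarray(y)
    units = np.asarray(units)
    if scheme.unit == "window":
        unit_ids = np.arange(y.size)
    else:
        _, unit_ids = np.unique(units, return_inverse=True)
    uniq = np.unique(unit_ids)
    unit_labels = np.array([y[unit_ids == u][0] for u in uniq])
    folds = []
    if scheme.kind == "loocv":
        for u in uniq:
            test = np.nonzero(unit_ids == u)[0]
            train = np.nonzero(unit_ids != u)[0]
            folds.append((train, test))
        return folds
    counts = np.unique(unit_labels, return_counts=True)[1]
    if counts.min() < scheme.k:
        raise ValueError(
            f"k-fold CV needs >= {scheme.k} units per class; smallest class has "
            f"{counts.min()}"
        )
    if scheme.stratified:
        splitter = StratifiedKFold(n_splits=scheme.k, shuffle=True, random_state=scheme.seed)
        split = splitter.split(uniq.reshape(-1, 1), unit_labels)
    else:
        splitter = KFold(n_splits=scheme.k, shuffle=True, random_state=scheme.seed)
        split = splitter.split(uniq.reshape(-1, 1))
    for tr_u, te_u in split:
        train = np.nonzero(np.isin(unit_ids, uniq[tr_u]))[0]
        test = np.nonzero(np.isin(unit_ids, uniq[te_u]))[0]
        folds.append((train, test))
    return folds


def cross_validate(
    X: np.ndarray,
    y: np.ndarray,
    units: np.ndarray,
    scheme: CVScheme,
    make_pipeline: Callable[[], BaseEstimator],
    positive_label=None,
    task: str = "",
) -> EvalReport:
    """Binary cross-validated evaluation with per-fold pipeline refitting.

    Every fit-transform stage in the pipeline (PCA enhancement, CNN FC
    training, SVM hyperparameter search) is refit on the training fold
    only; pooled test predictions and decision scores over all folds form
    the report.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    units = np.asarray(units)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("cross_validate is binary; use multiclass_evaluate")
    if positive_label is None:
        non_hc = [c for c in classes if c != "HC"]
        positive_label = non_hc[0] if len(non_hc) == 1 else classes[1]
    folds = make_folds(y, units, scheme)
    pooled_pred = np.empty(y.size, dtype=y.dtype)
    pooled_scores = np.empty(y.size, dtype=float)
    for fold_i, (train, test) in enumerate(folds):
        missing = set(classes) - set(y[train])
        if missing:
            raise ValueError(
                f"class {sorted(missing)} absent from training fold {fold_i}"
            )
        pipe = _fresh_pipeline(make_pipeline)
        pipe.fit(X[train], y[train])
        pooled_pred[test] = pipe.predict(X[test])
        scores = pipe.decision_function(X[test])
        fitted_classes = _final_classes(pipe)
        if fitted_classes is not None and fitted_classes[1] != positive_label:
            scores = -scores
        pooled_scores[test] = scores
    report = compute_metrics(
        y, pooled_scores, positive_label, y_pred=pooled_pred, task=task
    )
    report.meta.update({"scheme": scheme, "n_folds": len(folds)})
    return report


def _fresh_pipeline(make_pipeline) -> BaseEstimator:
    """Accept a prototype estimator or a zero-arg factory; return a fresh clone."""
    if isinstance(make_pipeline, BaseEstimator):
        return clone(make_pipeline)
    return clone(make_pipeline())


def _final_classes(pipe):
    est = pipe
    if hasattr(est, "steps"):
        est = est.steps[-1][1]
    return getattr(est, "classes_", None)


def multiclass_evaluate(
    X: np.ndarray,
    y: np.ndarray,
    units: np.ndarray,
    scheme: CVScheme,
    make_pipeline: Callable[[], BaseEstimator],
) -> EvalReport:
    """Multi-class cross-validated evaluation with one-vs-rest reporting.

    Predictions come from the SVC's one-vs-one vote aggregation; per-class
    sensitivity / specificity / accuracy / AUC and Youden J are computed
    one-vs-rest from the pooled predictions and ovr decision scores.
    """
    X = np.asarray(X)
    y = np.asarray(y)
    classes = np.unique(y)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    folds = make_folds(y, np.asarray(units), scheme)
    pooled_pred = np.empty(y.size, dtype=y.dtype)
    pooled_scores = np.empty((y.size, classes.size), dtype=float)
    for fold_i, (train, test) in enumerate(folds):
        missing = set(classes) - set(y[train])
        if missing:
            raise ValueError(
                f"class {sorted(missing)} absent from training fold {fold_i}"
            )
        pipe = _fresh_pipeline(make_pipeline)
        pipe.fit(X[train], y[train])
        pooled_pred[test] = pipe.predict(X[test])
        scores = pipe.decision_function(X[test])
        fitted = _final_classes(pipe)
        cols = [list(fitted).index(c) for c in classes]
        pooled_scores[test] = np.atleast_2d(scores)[:, cols]
    confusion = np.zeros((classes.size, classes.size), dtype=int)
    for i, ct in enumerate(classes):
        for j, cp in enumerate(classes):
            confusion[i, j] = int(((y == ct) & (pooled_pred == cp)).sum())
    per_class = {}
    for j, cls in enumerate(classes):
        y_bin = np.where(y == cls, "pos", "rest")
        pred_bin = np.where(pooled_pred == cls, "pos", "rest")
        per_class[cls] = compute_metrics(
            y_bin, pooled_scores[:, j], "pos", y_pred=pred_bin,
            task=f"{cls} vs rest",
        )
    overall_acc = 100.0 * np.trace(confusion) / y.size
    mean_j = float(np.mean([r.youden_j for r in per_class.values()]))
    report = EvalReport(
        task="multiclass " + "/".join(map(str, classes)),
        classes=tuple(classes),
        confusion=confusion,
        sensitivity=float(np.mean([r.sensitivity for r in per_class.values()])),
        specificity=float(np.mean([r.specificity for r in per_class.values()])),
        accuracy=overall_acc,
        auc=float(np.mean([r.auc for r in per_class.values()])),
        youden_j=mean_j,
        n_test=int(y.size),
        per_class=per_class,
        meta={"scheme": scheme, "n_folds": len(folds)},
    )
    return report
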