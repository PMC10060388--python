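"""Age-class discrimination from PC scores: LDA and SVM battery.

Four classifiers are compared for separating adult from infant faces in the
space of relative-warp scores: linear discriminant analysis, a linear SVM
with default cost, and linear/RBF SVMs with cost (and gamma) tuned by an
exhaustive power-of-two grid search under stratified fourfold
cross-validation.  Reported accuracy and AUC are cross-validated (held-out);
training-set metrics are also emitted, clearly labeled, since a tuned RBF
SVM trivially approaches training accuracy 1.

Features are standardized per column, with the scaler fit on training folds
only — raw PC scores have widely different variances, which would break a
shared gamma grid.  AUC uses the rank-sum (Mann-Whitney) formulation over
pooled out-of-fold decision scores, with ties given half credit.  The
positive class is "infant" throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

KINDS = ("lda", "linear_svm_untuned", "linear_svm_tuned", "rbf_svm_tuned")
TUNED_KINDS = ("linear_svm_tuned", "rbf_svm_tuned")
#: simplicity order used for tie-breaking in model selection
SIMPLICITY = {"lda": 0, "linear_svm_untuned": 1, "linear_svm_tuned": 2, "rbf_svm_tuned": 3}
POSITIVE_CLASS = "infant"


@dataclass(frozen=True)
class ClassifierSpec:
    """A concrete classifier choice: kind plus hyperparameters.

    ``cost``/``gamma`` are positive reals after tuning, or the string
    ``"default"`` (cost 1, scikit-learn's ``gamma="scale"``) for untuned kinds.
    """

    kind: str
    cost: float | str = "default"
    gamma: float | str = "default"

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise ValueError(f"unknown classifier kind {self.kind!r}")


@dataclass
class EvalResult:
    spec: ClassifierSpec
    features_used: tuple[int, ...]
    accuracy: float
    auc: float
    per_fold: list[tuple[float, float]]
    seed: int
    train_accuracy: float = float("nan")
    train_auc: float = float("nan")
    extras: dict = field(default_factory=dict)


def _make_estimator(spec: ClassifierSpec):
    cost = 1.0 if spec.cost == "default" else float(spec.cost)
    gamma = "scale" if spec.gamma == "default" else float(spec.gamma)
    if spec.kind == "lda":
        return LinearDiscriminantAnalysis()
    if spec.kind in ("linear_svm_untuned", "linear_svm_tuned"):
        return SVC(kernel="linear", C=cost)
    if spec.kind == "rbf_svm_tuned":
        return SVC(kernel="rbf", C=cost, gamma=gamma)
    raise ValueError(spec.kind)


def _binary_labels(labels: np.ndarray) -> np.ndarray:
    labels = np.asarray(labels)
    if labels.dtype.kind in "USO":
        return (labels == POSITIVE_CLASS).astype(int)
    return labels.astype(int)


def rank_auc(scores: np.ndarray, y: np.ndarray) -> float:
    """Mann-Whitney AUC of continuous scores for binary labels (ties: half credit)."""
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = y.size - n1
    if n1 == 0 or n0 == 0:
        return float("nan")
    ranks = rankdata(scores)
    return float((ranks[y == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


def _standardize_pair(train: np.ndarray, test: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    mu = train.mean(axis=0)
    sd = train.std(axis=0)
    sd[sd == 0] = 1.0
    return (train - mu) / sd, (test - mu) / sd


def _cv_scores(
    features: np.ndarray,
    y: np.ndarray,
    spec: ClassifierSpec,
    folds: int,
    seed: int,
    standardize: bool,
) -> tuple[np.ndarray, np.ndarray, list[tuple[float, float]]]:
    """Out-of-fold decision scores and predictions under stratified k-fold CV."""
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    oof_scores = np.empty(y.size)
    oof_pred = np.empty(y.size, dtype=int)
    per_fold = []
    for train_idx, test_idx in skf.split(features, y):
        xtr, xte = features[train_idx], features[test_idx]
        if standardize:
            xtr, xte = _standardize_pair(xtr, xte)
        est = _make_estimator(spec)
        est.fit(xtr, y[train_idx])
        pred = est.predict(xte)
        dec = est.decision_function(xte)
        oof_pred[test_idx] = pred
        oof_scores[test_idx] = dec
        per_fold.append(
            (float(np.mean(pred == y[test_idx])), rank_auc(dec, y[test_idx]))
        )
    return oof_scores, oof_pred, per_fold


def tune_hyperparameters(
    features: np.ndarray,
    labels: np.ndarray,
    kind: str,
    seed: int = 0,
    folds: int = 4,
    grid_min_exp: int = -10,
    grid_max_exp: int = 10,
    standardize: bool = True,
) -> ClassifierSpec:
    """Exhaustive power-of-two grid search for SVM cost (and RBF gamma).

    The grid is ``2**i`` for integer ``i`` in [grid_min_exp, grid_max_exp]
    (21 cost values by default; 441 cost x gamma pairs for the RBF kernel).
    Selection maximizes mean stratified fourfold cross-validated accuracy;
    ties break toward smaller cost, then smaller gamma.
    """
    if kind not in TUNED_KINDS:
        raise ValueError(f"kind {kind!r} is not a tuned kind")
    features = np.asarray(features, float)
    if features.ndim == 1:
        features = features[:, None]
    y = _binary_labels(labels)
    if y.size < 2 * folds:
        raise ValueError(f"need at least {2 * folds} samples for {folds}-fold tuning")
    grid = [2.0**i for i in range(grid_min_exp, grid_max_exp + 1)]
    gammas = grid if kind == "rbf_svm_tuned" else [None]
    best_acc = -np.inf
    best: tuple[float, float | None] = (grid[0], gammas[0])
    for cost in grid:
        for gamma in gammas:
            spec = ClassifierSpec(
                kind=kind, cost=cost, gamma="default" if gamma is None else gamma
            )
            _, pred, _ = _cv_scores(features, y, spec, folds, seed, standardize)
            acc = float(np.mean(pred == y))
            if acc > best_acc:  # iteration order implements the tie-break
                best_acc = acc
                best = (cost, gamma)
    return ClassifierSpec(
        kind=kind, cost=best[0], gamma="default" if best[1] is None else best[1]
    )


def evaluate(
    features: np.ndarray,
    labels: np.ndarray,
    spec: ClassifierSpec,
    folds: int = 4,
    seed: int = 0,
    standardize: bool = True,
    features_used: tuple[int, ...] | None = None,
) -> EvalResult:
    """Stratified k-fold cross-validated accuracy and AUC for one classifier.

    Accuracy is the pooled fraction correct over held-out folds; AUC is the
    rank-sum statistic of the pooled out-of-fold decision scores.  Training
    metrics (model fit on all data) are reported separately.
    """
    features = np.asarray(features, float)
    if features.ndim == 1:
        features = features[:, None]
    y = _binary_labels(labels)
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")
    if np.any(features.std(axis=0) == 0):
        warnings.warn("constant feature column; classifier may be degenerate", stacklevel=2)
    oof_scores, oof_pred, per_fold = _cv_scores(features, y, spec, folds, seed, standardize)
    accuracy = float(np.mean(oof_pred == y))
    auc = rank_auc(oof_scores, y)

    xtr = features
    if standardize:
        xtr, _ = _standardize_pair(features, features)
    est = _make_estimator(spec)
    est.fit(xtr, y)
    train_pred = est.predict(xtr)
    train_dec = est.decision_function(xtr)
    return EvalResult(
        spec=spec,
        features_used=features_used or tuple(range(features.shape[1])),
        accuracy=accuracy,
        auc=auc,
        per_fold=per_fold,
        seed=seed,
        train_accuracy=float(np.mean(train_pred == y)),
        train_auc=rank_auc(train_dec, y),
    )


def select_best(results: list[EvalResult]) -> ClassifierSpec:
    """Pick the best classifier: highest accuracy, then AUC, then simplicity."""
    if not results:
        raise ValueError("no results to select from")
    best = max(
        results,
        key=lambda r: (r.accuracy, r.auc, -SIMPLICITY[r.spec.kind]),
    )
    return best.spec


def model_battery(
    features: np.ndarray,
    labels: np.ndarray,
    folds: int = 4,
    seed: int = 0,
    grid_min_exp: int = -10,
    grid_max_exp: int = 10,
    standardize: bool = True,
) -> list[EvalResult]:
    """Fit and evaluate the four-model battery on one feature matrix."""
    results = []
    for kind in KINDS:
        if kind in TUNED_KINDS:
            spec = tune_hyperparameters(
                features, labels, kind, seed=seed, folds=folds,
                grid_min_exp=grid_min_exp, grid_max_exp=grid_max_exp,
                standardize=standardize,
            )
        else:
            spec = ClassifierSpec(kind=kind)
        results.append(
            evaluate(features, labels, spec, folds=folds, seed=seed, standardize=standardize)
        )
    return results
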