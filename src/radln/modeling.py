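"""Classifier evaluation under stratified cross-validation.

SVM, KNN and LDA are trained on standardized features inside each training
fold and evaluated on pooled out-of-fold predictions (micro-averaged
accuracy, sensitivity, specificity in percent, AUC from the continuous
decision scores).  Also: morphology-vs-texture ablations on identical folds
and the per-feature single-factor screen.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.metrics import roc_auc_score, roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .selection import choose_lambda_cv, standardize_features

__all__ = [
    "ClassifierSpec",
    "CVReport",
    "make_stratified_folds",
    "fit_predict",
    "confusion_and_auc",
    "cross_validate",
    "ablation_compare",
    "single_feature_screen",
]


@dataclass
class ClassifierSpec:
    """One of the three study classifiers with its hyperparameters.

    Defaults (unstated in the source study): SVM with RBF kernel, C=1,
    gamma='scale'; KNN with k=5 and Euclidean metric; plain LDA.  Scores for
    ROC: SVM signed decision value, KNN positive-neighbor fraction, LDA
    posterior probability.
    """

    kind: str = "svm"
    svm_kernel: str = "rbf"
    svm_C: float = 1.0
    svm_gamma: str | float = "scale"
    knn_k: int = 5
    knn_metric: str = "euclidean"

    def __post_init__(self) -> None:
        if self.kind not in ("svm", "knn", "lda"):
            raise ValueError(f"kind must be svm|knn|lda, got {self.kind}")
        if self.kind == "knn" and self.knn_k < 1:
            raise ValueError("knn_k must be >= 1")
        if self.kind == "svm" and self.svm_C <= 0:
            raise ValueError("svm_C must be > 0")

    def build(self):
        if self.kind == "svm":
            return SVC(kernel=self.svm_kernel, C=self.svm_C, gamma=self.svm_gamma)
        if self.kind == "knn":
            return KNeighborsClassifier(n_neighbors=self.knn_k, metric=self.knn_metric)
        return LinearDiscriminantAnalysis()


@dataclass
class CVReport:
    """Pooled out-of-fold evaluation of one classifier / feature set."""

    y_true: np.ndarray
    y_pred: np.ndarray
    scores: np.ndarray
    fold_ids: np.ndarray
    accuracy: float          # percent
    sensitivity: float       # percent
    specificity: float       # percent
    auc: float
    roc_points: np.ndarray   # (fpr, tpr) rows
    seed: int | None = None
    spec: ClassifierSpec | None = None
    feature_names: list[str] = field(default_factory=list)

    def metrics(self) -> dict[str, float]:
        return {"accuracy": self.accuracy, "sensitivity": self.sensitivity,
                "specificity": self.specificity, "auc": self.auc}


def make_stratified_folds(labels, k: int = 5, seed: int = 0) -> np.ndarray:
    """Deterministic stratified fold assignment (0..k-1 per subject)."""
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError("need both classes for stratified folds")
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) is below the fold count {k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    assignment = np.empty(len(y), dtype=int)
    for f, (_, te) in enumerate(skf.split(np.zeros((len(y), 1)), y)):
        assignment[te] = f
    return assignment


def fit_predict(spec: ClassifierSpec, train_X: np.ndarray, train_y: np.ndarray,
                test_X: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Train on one fold, return test labels and continuous risk scores."""
    train_y = np.asarray(train_y)
    if len(np.unique(train_y)) < 2:
        raise ValueError("training fold contains a single class")
    model = spec.build()
    model.fit(train_X, train_y)
    pred = model.predict(test_X)
    if spec.kind == "svm":
        scores = model.decision_function(test_X)
    else:
        scores = model.predict_proba(test_X)[:, 1]
    return pred, scores


def confusion_and_auc(y_true: np.ndarray, y_pred: np.ndarray, scores: np.ndarray
                      ) -> dict[str, float | np.ndarray]:
    """Pooled confusion metrics (percent) and rank-based AUC with midrank ties."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    scores = np.asarray(scores)
    if not (len(y_true) == len(y_pred) == len(scores)):
        raise ValueError("y_true, y_pred and scores must have equal length")
    if len(np.unique(y_true)) < 2:
        raise ValueError("y_true contains a single class")
    tp = int(np.sum((y_true == 1) & (y_pred == 1)))
    tn = int(np.sum((y_true == 0) & (y_pred == 0)))
    fp = int(np.sum((y_true == 0) & (y_pred == 1)))
    fn = int(np.sum((y_true == 1) & (y_pred == 0)))
    fpr, tpr, _ = roc_curve(y_true, scores)
    return {
        "accuracy": 100.0 * (tp + tn) / len(y_true),
        "sensitivity": 100.0 * tp / (tp + fn),
        "specificity": 100.0 * tn / (tn + fp),
        "auc": float(roc_auc_score(y_true, scores)),
        "roc_points": np.column_stack([fpr, tpr]),
    }


def cross_validate(spec: ClassifierSpec, X: pd.DataFrame, y, folds: int = 5,
                   seed: int = 0, select: str | list[str] | None = None,
                   selection_folds: int = 10) -> CVReport:
    """Stratified K-fold evaluation with per-fold standardization.

    ``select``:
      * None — use all columns of X;
      * a list of feature names — use that fixed subset (e.g. a whole-data
        LASSO support; leaks selection information into the folds, as the
        source analysis appears to have done);
      * "per_fold" — rerun LASSO selection inside each training fold.
    """
    y = np.asarray(y)
    assignment = make_stratified_folds(y, k=folds, seed=seed)
    n = len(y)
    pred = np.empty(n, dtype=int)
    scores = np.empty(n, dtype=float)
    feature_names = list(X.columns)
    for f in range(folds):
        te = assignment == f
        tr = ~te
        X_tr, X_te = X.loc[tr], X.loc[te]
        if select == "per_fold":
            sel = choose_lambda_cv(X_tr, y[tr], folds=selection_folds, seed=seed)
            cols = sel.selected_features or list(X.columns)
            X_tr, X_te = X_tr[cols], X_te[cols]
        elif isinstance(select, (list, tuple)):
            X_tr, X_te = X_tr[list(select)], X_te[list(select)]
        Z_tr, sparams = standardize_features(X_tr)
        Z_te, _ = standardize_features(X_te, params=sparams)
        pred[te], scores[te] = fit_predict(spec, Z_tr.to_numpy(), y[tr],
                                           Z_te.to_numpy())
    m = confusion_and_auc(y, pred, scores)
    return CVReport(y_true=y, y_pred=pred, scores=scores, fold_ids=assignment,
                    accuracy=m["accuracy"], sensitivity=m["sensitivity"],
                    specificity=m["specificity"], auc=m["auc"],
                    roc_points=m["roc_points"], seed=seed, spec=spec,
                    feature_names=list(select) if isinstance(select, (list, tuple))
                    else feature_names)


def ablation_compare(X: pd.DataFrame, y, feature_groups: dict[str, list[str]],
                     spec: ClassifierSpec | None = None, folds: int = 5,
                     seed: int = 0) -> dict[str, CVReport]:
    """One CVReport per named feature group, on identical folds."""
    spec = spec or ClassifierSpec("svm")
    for name, cols in feature_groups.items():
        if not cols:
            raise ValueError(f"feature group '{name}' is empty")
        missing = set(cols) - set(X.columns)
        if missing:
            raise ValueError(f"group '{name}' names unknown features: {sorted(missing)}")
    return {name: cross_validate(spec, X, y, folds=folds, seed=seed, select=list(cols))
            for name, cols in feature_groups.items()}


def single_feature_screen(X: pd.DataFrame, y, spec: ClassifierSpec | None = None,
                          folds: int = 5, seed: int = 0) -> pd.DataFrame:
    """Cross-validated accuracy and AUC of every feature used alone.

    The same classifier kind and the same fold assignment are used for every
    feature, so rows are comparable.
    """
    spec = spec or ClassifierSpec("svm")
    y = np.asarray(y)
    if min(np.bincount(y)) < 2:
        raise ValueError("need >= 2 subjects per class")
    rows = []
    for feat in X.columns:
        rep = cross_validate(spec, X[[feat]], y, folds=folds, seed=seed)
        rows.append({"feature": feat, "accuracy": rep.accuracy, "auc": rep.auc})
    return pd.DataFrame(rows).set_index("feature")
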