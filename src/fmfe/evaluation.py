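"""Classifier benchmarking and the multiclass metric suite.

Metrics are computed one-vs-rest from the pooled confusion matrix:

    R_c = TP / (TP + FN)          (recall = sensitivity)
    P_c = TP / (TP + FP)
    specificity_c = TN / (FP + TN)
    macro-R, macro-P, macro-sensitivity, macro-specificity: unweighted means
    accuracy = trace / total

Cross-validation is stratified ten-fold with a fixed seed; grid search, when
enabled, is nested inside each training fold.  Feature matrices are z-score
standardized inside each training fold for SVM/KNN/MLP (fit on train, applied
to test); random forests run on unscaled features.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.metrics import confusion_matrix as sk_confusion_matrix
from sklearn.metrics import roc_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import ConfigError, ValidationError

CLASSIFIERS = ("svm", "knn", "rf", "mlp")
META_COLUMNS = ("id", "label")

#: default nested grid-search spaces (conventional ranges, config-overridable)
DEFAULT_GRIDS: dict[str, dict] = {
    "svm": {"model__C": [0.1, 1.0, 10.0, 100.0],
            "model__gamma": ["scale", 0.01, 0.001]},
    "knn": {"model__n_neighbors": [1, 3, 5, 7, 9]},
    "rf": {"model__n_estimators": [100, 300, 500],
           "model__max_depth": [None, 10, 20]},
    "mlp": {"model__hidden_layer_sizes": [(50,), (100,), (100, 50)]},
}


@dataclass
class ConfusionMatrix:
    """Row = true class, column = predicted class."""

    counts: np.ndarray
    class_names: list[str]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        if self.counts.ndim != 2 or self.counts.shape[0] != self.counts.shape[1]:
            raise ValidationError("confusion matrix must be square")
        if np.any(self.counts < 0):
            raise ValidationError("confusion matrix counts must be nonnegative")
        if len(self.class_names) != self.counts.shape[0]:
            raise ValidationError("class names must match matrix size")

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class EvalReport:
    accuracy: float
    macro_precision: float
    macro_recall: float
    macro_sensitivity: float
    macro_specificity: float
    per_class: dict[str, dict[str, float]]
    confusion: ConfusionMatrix
    undefined_precision_classes: list[str] = field(default_factory=list)
    per_fold: list[ConfusionMatrix] = field(default_factory=list)
    auc_one_vs_rest: dict[str, float] = field(default_factory=dict)
    selected_params: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_sensitivity": self.macro_sensitivity,
            "macro_specificity": self.macro_specificity,
            "per_class": self.per_class,
            "class_names": self.confusion.class_names,
            "confusion_matrix": self.confusion.counts.tolist(),
            "per_fold_matrices": [m.counts.tolist() for m in self.per_fold],
            "undefined_precision_classes": self.undefined_precision_classes,
            "auc_one_vs_rest": self.auc_one_vs_rest,
            "selected_params": self.selected_params,
        }


def compute_metrics(matrix: ConfusionMatrix) -> EvalReport:
    """One-vs-rest metric suite from a pooled confusion matrix.

    A class never predicted (TP + FP = 0) gets precision 0 and is flagged in
    ``undefined_precision_classes``.
    """
    counts = matrix.counts.astype(np.float64)
    total = counts.sum()
    if total <= 0:
        raise ValidationError("confusion matrix is empty")
    per_class: dict[str, dict[str, float]] = {}
    undefined: list[str] = []
    recalls, precisions, specificities = [], [], []
    for i, name in enumerate(matrix.class_names):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        recall = tp / (tp + fn) if tp + fn > 0 else 0.0
        if tp + fp > 0:
            precision = tp / (tp + fp)
        else:
            precision = 0.0
            undefined.append(name)
        specificity = tn / (fp + tn) if fp + tn > 0 else 0.0
        per_class[name] = {"recall": recall, "precision": precision,
                           "sensitivity": recall, "specificity": specificity}
        recalls.append(recall)
        precisions.append(precision)
        specificities.append(specificity)
    return EvalReport(
        accuracy=float(np.trace(counts) / total),
        macro_precision=float(np.mean(precisions)),
        macro_recall=float(np.mean(recalls)),
        macro_sensitivity=float(np.mean(recalls)),
        macro_specificity=float(np.mean(specificities)),
        per_class=per_class,
        confusion=matrix,
        undefined_precision_classes=undefined,
    )


def make_classifier(name: str, seed: int = 0):
    """A ready-to-fit pipeline for one of svm | knn | rf | mlp."""
    if name == "svm":
        return Pipeline([("scale", StandardScaler()),
                         ("model", SVC(kernel="rbf", C=10.0, gamma="scale",
                                       random_state=seed))])
    if name == "knn":
        return Pipeline([("scale", StandardScaler()),
                         ("model", KNeighborsClassifier(n_neighbors=5))])
    if name == "rf":
        return Pipeline([("model", RandomForestClassifier(
            n_estimators=300, random_state=seed, n_jobs=1))])
    if name == "mlp":
        return Pipeline([("scale", StandardScaler()),
                         ("model", MLPClassifier(hidden_layer_sizes=(100,),
                                                 max_iter=800,
                                                 random_state=seed))])
    raise ConfigError(f"unknown classifier {name!r} (choose from {CLASSIFIERS})")


def feature_matrix(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Split a feature table into (X, y, feature_names)."""
    if "label" not in table.columns:
        raise ValidationError("feature table needs a 'label' column")
    feature_cols = [c for c in table.columns if c not in META_COLUMNS]
    X = table[feature_cols].to_numpy(dtype=np.float64)
    y = table["label"].to_numpy()
    if not np.all(np.isfinite(X)):
        raise ValidationError("feature table contains undefined values")
    return X, y, feature_cols


def cross_validate(table: pd.DataFrame, classifier: str = "rf",
                   n_folds: int = 10, seed: int = 0,
                   grid_search: bool = False,
                   param_grid: dict | None = None) -> EvalReport:
    """Stratified k-fold evaluation with pooled and per-fold confusion matrices.

    When ``grid_search`` is on, hyperparameters are selected inside each
    training fold by an inner 3-fold grid search, and the winning parameters
    are recorded per fold.
    """
    X, y, _ = feature_matrix(table)
    classes = sorted(np.unique(y).tolist())
    smallest = min(np.sum(y == c) for c in classes)
    if smallest < n_folds:
        raise ValidationError(
            f"every class needs at least {n_folds} samples (smallest has {smallest})")
    base = make_classifier(classifier, seed)
    grid = param_grid if param_grid is not None else DEFAULT_GRIDS[classifier]
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    pooled = np.zeros((len(classes), len(classes)), dtype=np.int64)
    per_fold: list[ConfusionMatrix] = []
    selected: list[dict] = []
    for train_idx, test_idx in skf.split(X, y):
        model = clone(base)
        if grid_search:
            search = GridSearchCV(model, grid, cv=3, n_jobs=1)
            search.fit(X[train_idx], y[train_idx])
            model = search.best_estimator_
            selected.append(dict(search.best_params_))
        else:
            model.fit(X[train_idx], y[train_idx])
        predictions = model.predict(X[test_idx])
        fold = sk_confusion_matrix(y[test_idx], predictions, labels=classes)
        per_fold.append(ConfusionMatrix(fold, classes))
        pooled += fold
    report = compute_metrics(ConfusionMatrix(pooled, classes))
    report.per_fold = per_fold
    report.selected_params = selected
    return report


def _binary_auc(y_true: np.ndarray, scores: np.ndarray) -> float:
    """Trapezoidal area under the ROC curve of one binary problem."""
    fpr, tpr, _ = roc_curve(y_true, scores)
    return float(np.trapezoid(tpr, fpr))


def roc_one_vs_rest(table: pd.DataFrame, classifier: str = "rf",
                    n_folds: int = 10, seed: int = 0) -> dict[str, float]:
    """Per-class one-vs-rest AUC from cross-validated continuous scores."""
    X, y, _ = feature_matrix(table)
    classes = sorted(np.unique(y).tolist())
    base = make_classifier(classifier, seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    scores = np.zeros((y.size, len(classes)))
    for train_idx, test_idx in skf.split(X, y):
        model = clone(base)
        model.fit(X[train_idx], y[train_idx])
        if hasattr(model, "predict_proba"):
            try:
                s = model.predict_proba(X[test_idx])
            except AttributeError:
                s = None
        else:
            s = None
        if s is None:
            if not hasattr(model, "decision_function"):
                raise ConfigError(
                    f"classifier {classifier!r} exposes no continuous score")
            s = model.decision_function(X[test_idx])
            if s.ndim == 1:
                s = np.column_stack([-s, s])
        scores[test_idx] = s
    return {cls: _binary_auc(y == cls, scores[:, j])
            for j, cls in enumerate(classes)}


@dataclass
class TTestResult:
    t: float
    p: float
    mean_a: float
    mean_b: float
    sem_a: float
    sem_b: float
    degenerate: bool = False


def feature_ttest(table: pd.DataFrame, feature_name: str,
                  class_a: str, class_b: str) -> TTestResult:
    """Welch two-sample t-test of one feature between two classes.

    Also reports the per-class mean and standard error.  Two constant groups
    with equal means are degenerate and return t=0, p=1 (flagged).
    """
    if feature_name not in table.columns:
        raise ValidationError(f"unknown feature {feature_name!r}")
    a = table.loc[table["label"] == class_a, feature_name].to_numpy(float)
    b = table.loc[table["label"] == class_b, feature_name].to_numpy(float)
    if a.size < 2 or b.size < 2:
        raise ValidationError("need at least 2 samples per class")
    sem_a = float(a.std(ddof=1) / np.sqrt(a.size))
    sem_b = float(b.std(ddof=1) / np.sqrt(b.size))
    if a.std(ddof=1) == 0.0 and b.std(ddof=1) == 0.0:
        if a.mean() == b.mean():
            return TTestResult(0.0, 1.0, float(a.mean()), float(b.mean()),
                               sem_a, sem_b, degenerate=True)
        t = np.inf if a.mean() > b.mean() else -np.inf
        return TTestResult(float(t), 0.0, float(a.mean()), float(b.mean()),
                           sem_a, sem_b, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return TTestResult(float(t), float(p), float(a.mean()), float(b.mean()),
                       sem_a, sem_b)
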