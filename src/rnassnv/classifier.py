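"""Weighted random-forest discrimination of true somatic SNVs from artifacts.

The learner is a random forest with inverse-class-frequency weights (the
1:8 TP:TN imbalance would otherwise bias it toward the artifact class),
preceded by recursive feature elimination with cross-validation (one
feature dropped per iteration, F1-scored) and a cross-validated grid
search over forest hyperparameters.

Metric formulas
---------------
The evaluation report implements the framework's printed definitions,
two of which differ from the textbook ones and are pinned by tests:

    precision = TP / (TP + FP)          recall = TP / (TP + FN)
    F1        = 2 P R / (P + R)
    FPR       = FP / (FP + TN)
    FNR       = FN / (FN + TN)          # not FN / (FN + TP)
    TNR       = TN / (FN + TN)          # not TN / (TN + FP)

PR-AUC uses the step-interpolation rule (no linear interpolation between
precision-recall points), which is the average-precision estimator.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.feature_selection import RFECV
from sklearn.metrics import precision_recall_curve
from sklearn.model_selection import GridSearchCV, StratifiedKFold, train_test_split
from sklearn.utils.validation import check_is_fitted

from .io_formats import ConfigurationError

POSITIVE, NEGATIVE = "TP", "TN"

#: default hyperparameter grid; the reference procedure names these knobs
DEFAULT_GRID = {
    "max_depth": [5, 10, 20, None],
    "min_samples_split": [2, 5, 10],
    "min_samples_leaf": [1, 2, 5],
    "max_features": ["sqrt", "log2"],
}


def _as_binary(y) -> np.ndarray:
    """Map labels to {0, 1} with TP/positive/True -> 1."""
    y = np.asarray(y)
    if y.dtype.kind in "biu":
        return y.astype(int)
    if y.dtype.kind == "f":
        return y.astype(int)
    mapping = {POSITIVE: 1, NEGATIVE: 0, "positive": 1, "negative": 0,
               "True": 1, "False": 0}
    try:
        return np.array([mapping[str(v)] for v in y], dtype=int)
    except KeyError as exc:
        raise ValueError(f"unrecognized label {exc.args[0]!r}") from exc


def _check_two_classes(y: np.ndarray) -> None:
    if len(np.unique(y)) < 2:
        raise ValueError("both classes must be present")


def _subsample(X: pd.DataFrame, y: np.ndarray, max_rows: Optional[int], seed: int):
    if max_rows is None or len(X) <= max_rows:
        return X, y
    X_sub, _, y_sub, _ = train_test_split(
        X, y, train_size=max_rows, stratify=y, random_state=seed,
    )
    return X_sub, y_sub


def select_features(
    X: pd.DataFrame,
    y,
    folds: int = 10,
    seed: int = 0,
    scoring: str = "f1",
    n_estimators: int = 50,
    max_rows: Optional[int] = None,
) -> list[str]:
    """Recursive feature elimination with cross-validation (step 1, F1).

    Returns the feature subset maximizing cross-validated F1. ``max_rows``
    optionally caps the number of (stratified) rows used during selection,
    which keeps large runs tractable without changing the procedure.
    """
    y = _as_binary(y)
    _check_two_classes(y)
    X, y = _subsample(X, y, max_rows, seed)
    estimator = RandomForestClassifier(
        n_estimators=n_estimators, class_weight="balanced",
        random_state=seed, n_jobs=1,
    )
    rfecv = RFECV(
        estimator, step=1, scoring=scoring,
        cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
        min_features_to_select=1,
    )
    rfecv.fit(X, y)
    return [name for name, keep in zip(X.columns, rfecv.support_) if keep]


def tune_hyperparameters(
    X: pd.DataFrame,
    y,
    grid: Optional[Mapping[str, Sequence]] = None,
    folds: int = 10,
    seed: int = 0,
    scoring: str = "f1",
    n_estimators: int = 100,
    max_rows: Optional[int] = None,
) -> dict:
    """Exhaustive cross-validated grid search; best by mean F1.

    Ties break toward the earlier point in grid order.
    """
    grid = dict(grid) if grid is not None else dict(DEFAULT_GRID)
    if not grid:
        raise ConfigurationError("hyperparameter grid must be nonempty")
    valid = set(RandomForestClassifier().get_params())
    unknown = set(grid) - valid
    if unknown:
        raise ConfigurationError(f"not random-forest parameters: {sorted(unknown)}")
    y = _as_binary(y)
    _check_two_classes(y)
    X, y = _subsample(X, y, max_rows, seed)
    estimator = RandomForestClassifier(
        n_estimators=n_estimators, class_weight="balanced",
        random_state=seed, n_jobs=1,
    )
    search = GridSearchCV(
        estimator, param_grid=grid, scoring=scoring,
        cv=StratifiedKFold(folds, shuffle=True, random_state=seed),
    )
    search.fit(X, y)
    return dict(search.best_params_)


@dataclass
class ModelBundle:
    """A fitted forest plus everything needed to apply it reproducibly."""

    model: RandomForestClassifier
    features: list[str]
    class_weight: object = "balanced"
    threshold: float = 0.5
    metadata: dict = field(default_factory=dict)

    def save(self, path) -> None:
        joblib.dump(self, path)

    @staticmethod
    def load(path) -> "ModelBundle":
        return joblib.load(path)


def train_classifier(
    X: pd.DataFrame,
    y,
    features: Sequence[str],
    params: Optional[Mapping] = None,
    class_weight="balanced",
    n_estimators: int = 300,
    seed: int = 0,
) -> ModelBundle:
    """Fit the weighted random forest on the selected features.

    ``class_weight='balanced'`` assigns each class a weight inversely
    proportional to its frequency, so at 1:8 imbalance the minority class
    weighs ~8x the majority.
    """
    features = list(features)
    if not features:
        raise ConfigurationError("selected feature list must be nonempty")
    y = _as_binary(y)
    _check_two_classes(y)
    params = dict(params or {})
    params.setdefault("n_estimators", n_estimators)
    model = RandomForestClassifier(
        class_weight=class_weight, random_state=seed, n_jobs=1, **params,
    )
    model.fit(X[features], y)
    return ModelBundle(
        model=model, features=features, class_weight=class_weight,
        metadata={"seed": seed, "params": params, "n_train": len(X)},
    )


def predict(
    bundle: ModelBundle,
    X: pd.DataFrame,
    threshold: Optional[float] = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Return (probabilities, classes); positive iff probability >= threshold."""
    threshold = bundle.threshold if threshold is None else threshold
    missing = [f for f in bundle.features if f not in X.columns]
    if missing:
        raise ConfigurationError(f"feature columns missing from matrix: {missing}")
    pos_index = int(np.where(bundle.model.classes_ == 1)[0][0])
    probs = bundle.model.predict_proba(X[bundle.features])[:, pos_index]
    return probs, probs >= threshold


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")


def compute_confusion(y_true, y_pred) -> ConfusionMatrix:
    """Count the 2x2 confusion table (rows true condition, columns predicted)."""
    y_true = _as_binary(y_true)
    y_pred = _as_binary(y_pred)
    if len(y_true) != len(y_pred):
        raise ValueError("truth and prediction vectors must align 1:1")
    return ConfusionMatrix(
        tp=int(np.sum((y_true == 1) & (y_pred == 1))),
        fp=int(np.sum((y_true == 0) & (y_pred == 1))),
        fn=int(np.sum((y_true == 1) & (y_pred == 0))),
        tn=int(np.sum((y_true == 0) & (y_pred == 0))),
    )


@dataclass
class MetricsReport:
    """The six report metrics; ``None`` marks an undefined (0/0) metric."""

    precision: Optional[float]
    recall: Optional[float]
    f1: Optional[float]
    fpr: Optional[float]
    fnr: Optional[float]
    tnr: Optional[float]
    pr_auc: Optional[float] = None

    def rounded(self, ndigits: int = 3) -> "MetricsReport":
        def r(v):
            return None if v is None else round(v, ndigits)
        return MetricsReport(r(self.precision), r(self.recall), r(self.f1),
                             r(self.fpr), r(self.fnr), r(self.tnr), r(self.pr_auc))


def _ratio(num: int, den: int) -> Optional[float]:
    return None if den == 0 else num / den


def compute_metrics(cm: ConfusionMatrix) -> MetricsReport:
    """The framework's metric formulas (note the FN+TN denominators)."""
    precision = _ratio(cm.tp, cm.tp + cm.fp)
    recall = _ratio(cm.tp, cm.tp + cm.fn)
    if precision is None or recall is None or (precision + recall) == 0:
        f1 = None
    else:
        f1 = 2 * precision * recall / (precision + recall)
    return MetricsReport(
        precision=precision,
        recall=recall,
        f1=f1,
        fpr=_ratio(cm.fp, cm.fp + cm.tn),
        fnr=_ratio(cm.fn, cm.fn + cm.tn),
        tnr=_ratio(cm.tn, cm.fn + cm.tn),
    )


@dataclass
class PrCurve:
    precision: np.ndarray
    recall: np.ndarray
    thresholds: np.ndarray
    auc: float


def pr_curve_auc(probabilities, y_true) -> PrCurve:
    """Precision-recall curve over all thresholds; step-rule area."""
    y = _as_binary(y_true)
    _check_two_classes(y)
    precision, recall, thresholds = precision_recall_curve(y, np.asarray(probabilities))
    # recall is decreasing along the returned arrays; the step rule sums
    # precision at each achieved recall increment (average precision)
    auc = float(-np.sum(np.diff(recall) * np.asarray(precision)[:-1]))
    return PrCurve(precision=precision, recall=recall, thresholds=thresholds, auc=auc)


def feature_importance(bundle: ModelBundle) -> pd.Series:
    """Gini impurity-based importances, normalized to sum to one."""
    check_is_fitted(bundle.model)
    imp = np.asarray(bundle.model.feature_importances_, dtype=float)
    total = imp.sum()
    if total > 0:
        imp = imp / total
    return pd.Series(imp, index=bundle.features).sort_values(ascending=False)
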