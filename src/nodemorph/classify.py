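"""SVM classification of node status and its evaluation.

Labels follow the clinical convention: +1 malignant, -1 benign.  Models
are support vector machines (linear or RBF kernel) with optional feature
standardization fitted on the training set.  Evaluation reports accuracy,
sensitivity and specificity from the 2x2 confusion table; leave-one-out
cross-validation (LOOCV) is the small-sample protocol used throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .errors import DataError, ParameterError

__all__ = [
    "SvmConfig",
    "EvalMetrics",
    "train_svm",
    "predict",
    "loocv",
    "evaluate",
]

_LABELS = (-1, 1)


@dataclass
class SvmConfig:
    """SVM hyperparameters: kernel in {linear, rbf}, cost C > 0, RBF
    bandwidth gamma (or "scale"), and whether to standardize features on
    the training set."""

    kernel: str = "rbf"
    cost: float = 1.0
    gamma: float | str = "scale"
    standardize: bool = True
    class_weight: str | None = None

    def validate(self) -> None:
        if self.kernel not in ("linear", "rbf"):
            raise ParameterError("kernel must be 'linear' or 'rbf'")
        if self.cost <= 0:
            raise ParameterError("cost must be positive")
        if isinstance(self.gamma, str) and self.gamma != "scale":
            raise ParameterError("gamma must be positive or 'scale'")
        if not isinstance(self.gamma, str) and self.gamma <= 0:
            raise ParameterError("gamma must be positive or 'scale'")


@dataclass
class EvalMetrics:
    """Accuracy / sensitivity / specificity plus the confusion table.

    A metric whose denominator is empty (no positives for sensitivity, no
    negatives for specificity) is reported as ``None``, never as 0.
    """

    accuracy: float | None
    sensitivity: float | None
    specificity: float | None
    tp: int
    fn: int
    fp: int
    tn: int

    def as_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "confusion": {"tp": self.tp, "fn": self.fn,
                          "fp": self.fp, "tn": self.tn},
        }


def _check_labels(y) -> np.ndarray:
    y = np.asarray(y)
    if not np.isin(y, _LABELS).all():
        raise DataError("labels must be -1 (benign) or +1 (malignant)")
    return y.astype(int)


def _as_matrix(X, active_features=None) -> pd.DataFrame:
    X = pd.DataFrame(X)
    if active_features is not None:
        active_features = list(active_features)
        missing = [f for f in active_features if f not in X.columns]
        if missing:
            raise DataError(f"missing features: {missing}")
        X = X[active_features]
    return X


def train_svm(X, y, active_features=None, config: SvmConfig | None = None):
    """Fit an SVM on ``X`` restricted to ``active_features``.

    ``X`` is a DataFrame (or convertible) of named features; the returned
    model remembers its feature list and, when standardization is on, the
    training-set mean/SD applied before the kernel.
    """
    config = config or SvmConfig()
    config.validate()
    X = _as_matrix(X, active_features)
    y = _check_labels(y)
    if len(X) != len(y):
        raise DataError("X and y length mismatch")
    if X.shape[1] == 0:
        raise DataError("active feature set is empty")
    if len(np.unique(y)) < 2:
        raise DataError("training data contains a single class")
    steps = []
    if config.standardize:
        steps.append(("scale", StandardScaler()))
    steps.append(("svm", SVC(kernel=config.kernel, C=config.cost,
                             gamma=config.gamma,
                             class_weight=config.class_weight)))
    model = Pipeline(steps)
    model.fit(X.to_numpy(), y)
    model.feature_names_ = list(X.columns)
    return model


def predict(model, X) -> np.ndarray:
    """Predict labels in {-1, +1} for samples with the model's features."""
    X = _as_matrix(X, getattr(model, "feature_names_", None))
    if len(X) == 0:
        return np.empty(0, dtype=int)
    return model.predict(X.to_numpy()).astype(int)


def loocv(X, y, active_features=None, config: SvmConfig | None = None,
          train_fn=None) -> EvalMetrics:
    """Leave-one-out cross-validation: n rounds of train-on-(n-1), predict-1.

    ``train_fn(X, y)`` may override the trainer (it must return an object
    accepted by :func:`predict`); by default an SVM with ``config`` is
    fitted per fold.  A fold whose training half degenerates to a single
    class is counted as an error with a warning.
    """
    config = config or SvmConfig()
    X = _as_matrix(X, active_features)
    y = _check_labels(y)
    n = len(X)
    if n < 3 or len(np.unique(y)) < 2:
        raise DataError("LOOCV needs n >= 3 with both classes present")
    if train_fn is None:
        def train_fn(Xtr, ytr):
            return train_svm(Xtr, ytr, config=config)
    preds = np.empty(n, dtype=int)
    for i in range(n):
        keep = np.arange(n) != i
        Xtr, ytr = X.iloc[keep], y[keep]
        try:
            model = train_fn(Xtr, ytr)
        except DataError:
            warnings.warn(f"LOOCV fold {i}: single-class training set; "
                          "fold counted as an error", stacklevel=2)
            preds[i] = -y[i]
            continue
        preds[i] = predict(model, X.iloc[[i]])[0]
    return evaluate(preds, y)


def evaluate(predictions, truth) -> EvalMetrics:
    """Confusion-table metrics with +1 = positive (malignant).

    accuracy = (TP+TN)/n, sensitivity = TP/(TP+FN),
    specificity = TN/(TN+FP); a metric with an empty denominator is
    ``None``.
    """
    predictions = _check_labels(predictions)
    truth = _check_labels(truth)
    if len(predictions) != len(truth):
        raise DataError("predictions and truth length mismatch")
    if len(truth) == 0:
        raise DataError("empty evaluation set")
    tp = int(((predictions == 1) & (truth == 1)).sum())
    fn = int(((predictions == -1) & (truth == 1)).sum())
    fp = int(((predictions == 1) & (truth == -1)).sum())
    tn = int(((predictions == -1) & (truth == -1)).sum())
    n_pos, n_neg = tp + fn, tn + fp
    return EvalMetrics(
        accuracy=(tp + tn) / len(truth),
        sensitivity=tp / n_pos if n_pos else None,
        specificity=tn / n_neg if n_neg else None,
        tp=tp, fn=fn, fp=fp, tn=tn,
    )
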