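"""Logistic classifier on the two signature scores, and balanced accuracy.

The feature space is deliberately tiny — (tumor_score, normal_score) per
cell — so a plain maximum-likelihood logistic fit with a weak L2 penalty is
all that is needed; no hyperparameter search is performed. Class order is
fixed as (normal, tumor): the tumor probability is always column 2.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.linear_model import LogisticRegression

from .errors import ConfigurationError, DegenerateTargetError, ValidationError
from .scoring import SignatureScores

CLASSES = ("normal", "tumor")

__all__ = ["ScoreClassifier", "balanced_accuracy", "CLASSES"]


def _features(scores) -> np.ndarray:
    if isinstance(scores, SignatureScores):
        return scores.as_features()
    x = np.asarray(scores, dtype=float)
    if x.ndim != 2:
        raise ValidationError("scores must be a 2-D (cells x features) array")
    return x


@dataclass
class ScoreClassifier:
    """Two-feature logistic model: P(tumor | tumor_score, normal_score)."""

    C: float = 1.0  # inverse L2 strength; weak penalty for numerical stability
    coefficients: np.ndarray | None = None  # shape (2,)
    intercept: float | None = None
    training_metadata: dict = field(default_factory=dict)

    @property
    def classes(self) -> tuple[str, str]:
        return CLASSES

    def fit(self, scores, labels) -> "ScoreClassifier":
        """Fit on per-cell scores against binary tumor labels.

        ``labels`` may be booleans (True = tumor) or the strings
        ``"tumor"``/``"normal"``. Deterministic given identical inputs.
        """
        x = _features(scores)
        if x.shape[1] != 2:
            raise ValidationError(f"expected 2 features, got {x.shape[1]}")
        if not np.all(np.isfinite(x)):
            raise ValidationError("scores contain NaN or infinite values")
        y = _binary_labels(labels)
        if len(y) != x.shape[0]:
            raise ValidationError("scores and labels differ in length")
        if len(np.unique(y)) < 2:
            raise DegenerateTargetError("training labels contain a single class")
        lr = LogisticRegression(C=self.C, solver="lbfgs", max_iter=1000)
        lr.fit(x, y)
        self.coefficients = lr.coef_.ravel().copy()
        self.intercept = float(lr.intercept_[0])
        self.training_metadata.update(
            {
                "n_cells": int(len(y)),
                "n_tumor": int(y.sum()),
                "n_normal": int(len(y) - y.sum()),
                "C": self.C,
                "solver": "lbfgs",
            }
        )
        return self

    # -- prediction -----------------------------------------------------
    def decision_function(self, scores) -> np.ndarray:
        self._check_fitted()
        x = _features(scores)
        if x.shape[1] != len(self.coefficients):
            raise ValidationError(
                f"feature mismatch: model has {len(self.coefficients)}, "
                f"input has {x.shape[1]}"
            )
        return x @ self.coefficients + self.intercept

    def predict_proba(self, scores) -> np.ndarray:
        """Per-cell class probabilities, columns ordered (normal, tumor)."""
        z = self.decision_function(scores)
        p_tumor = 1.0 / (1.0 + np.exp(-z))
        return np.column_stack([1.0 - p_tumor, p_tumor])

    def predict(self, scores) -> np.ndarray:
        """Boolean tumor calls (argmax of the two class probabilities)."""
        return self.decision_function(scores) > 0

    def _check_fitted(self):
        if self.coefficients is None:
            raise ConfigurationError("classifier is not fitted")

    # -- persistence ----------------------------------------------------
    def to_json(self, path: str | Path) -> None:
        self._check_fitted()
        payload = {
            "classes": list(CLASSES),
            "coefficients": list(map(float, self.coefficients)),
            "intercept": self.intercept,
            "C": self.C,
            "training_metadata": self.training_metadata,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "ScoreClassifier":
        payload = json.loads(Path(path).read_text())
        model = cls(C=payload.get("C", 1.0))
        model.coefficients = np.asarray(payload["coefficients"], dtype=float)
        model.intercept = float(payload["intercept"])
        model.training_metadata = payload.get("training_metadata", {})
        return model


def _binary_labels(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype == bool:
        return arr.astype(int)
    if arr.dtype.kind in "iu":
        if not set(np.unique(arr)) <= {0, 1}:
            raise ValidationError("integer labels must be 0/1")
        return arr.astype(int)
    lowered = np.char.lower(arr.astype(str))
    unknown = set(np.unique(lowered)) - set(CLASSES)
    if unknown:
        raise ValidationError(f"unknown labels {sorted(unknown)}; expected {CLASSES}")
    return (lowered == "tumor").astype(int)


def balanced_accuracy(truth, predicted) -> float:
    """Mean of per-class recalls — insensitive to class imbalance.

    Raises when a truth class is absent (its recall would be undefined).
    """
    t = np.asarray(truth).astype(bool)
    p = np.asarray(predicted).astype(bool)
    if t.shape != p.shape:
        raise ValidationError("truth and prediction differ in length")
    if t.all() or (~t).all():
        raise ValidationError("balanced accuracy undefined: a truth class is absent")
    recall_pos = (t & p).sum() / t.sum()
    recall_neg = (~t & ~p).sum() / (~t).sum()
    return float((recall_pos + recall_neg) / 2.0)
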