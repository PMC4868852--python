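"""Linear-SVM classification, hybrid score fusion, and evaluation metrics.

Decision scores from a classifier trained on the BoVW representation and
one trained on the VLAD representation are fused as a convex combination
``S = α·S_BoVW + (1−α)·S_VLAD``; the weight α is chosen adaptively on
inner-validation scores.  Metrics follow the standard confusion-matrix
formulas (ACC, SEN, SPEC, BAC, PPV, NPV) plus the tie-averaged rank AUC.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score
from sklearn.svm import SVC

from .exceptions import ConfigurationError, InputDataError

__all__ = [
    "ScoreSet",
    "ConfusionCounts",
    "train_linear_svm",
    "select_fusion_weight",
    "fuse_scores",
    "predict_from_scores",
    "compute_metrics",
    "METRIC_NAMES",
]

METRIC_NAMES = ("ACC", "SEN", "SPEC", "BAC", "PPV", "NPV", "AUC")

DEFAULT_ALPHA_GRID = tuple(float(a) for a in np.round(np.linspace(0.0, 1.0, 11), 1))
DEFAULT_C_GRID = (0.01, 0.1, 1.0, 10.0)


@dataclass(frozen=True)
class ScoreSet:
    """Decision values of the two encodings plus their fusion weight."""

    s_bovw: np.ndarray
    s_vlad: np.ndarray
    alpha: float

    @property
    def s_fused(self) -> np.ndarray:
        return fuse_scores(self.s_bovw, self.s_vlad, self.alpha)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def train_linear_svm(X: np.ndarray, y: np.ndarray, C: float = 1.0,
                     tol: float = 1e-6) -> SVC:
    """Soft-margin linear SVM exposing a signed decision value per subject.

    Labels must be ±1 with both classes present; positive decision values
    predict the positive class.
    """
    if C <= 0:
        raise ConfigurationError(f"C must be > 0, got {C}")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if set(np.unique(y)) != {-1, 1}:
        raise InputDataError(
            "labels must be ±1 with both classes present, got "
            f"{sorted(np.unique(y).tolist())}"
        )
    model = SVC(kernel="linear", C=C, tol=tol)
    model.fit(X, y)
    return model


def fuse_scores(s_bovw: np.ndarray, s_vlad: np.ndarray, alpha: float) -> np.ndarray:
    """Convex combination ``α·s_bovw + (1−α)·s_vlad`` element-wise."""
    s_bovw = np.asarray(s_bovw, dtype=float)
    s_vlad = np.asarray(s_vlad, dtype=float)
    if s_bovw.shape != s_vlad.shape:
        raise InputDataError(
            f"score lengths differ: {s_bovw.shape} vs {s_vlad.shape}"
        )
    if not 0.0 <= alpha <= 1.0:
        raise ConfigurationError(f"alpha must be in [0, 1], got {alpha}")
    return alpha * s_bovw + (1.0 - alpha) * s_vlad


def predict_from_scores(scores: np.ndarray) -> np.ndarray:
    """Sign rule with the tie (score exactly 0) mapped to the positive class."""
    return np.where(np.asarray(scores) >= 0, 1, -1)


def select_fusion_weight(
    inner_scores_bovw: np.ndarray,
    inner_scores_vlad: np.ndarray,
    inner_labels: np.ndarray,
    grid=DEFAULT_ALPHA_GRID,
) -> float:
    """Grid α maximizing inner-validation accuracy of the fused sign rule.

    Ties are broken toward 0.5, then toward the smaller α for determinism.
    """
    grid = tuple(grid)
    if len(grid) == 0:
        raise ConfigurationError("alpha grid must be nonempty")
    if any(not 0.0 <= a <= 1.0 for a in grid):
        raise ConfigurationError(f"alpha grid must lie in [0, 1], got {grid}")
    y = np.asarray(inner_labels)
    accs = []
    for alpha in grid:
        pred = predict_from_scores(
            fuse_scores(inner_scores_bovw, inner_scores_vlad, alpha)
        )
        accs.append(float(np.mean(pred == y)))
    best = max(accs)
    candidates = [a for a, acc in zip(grid, accs) if acc == best]
    return min(candidates, key=lambda a: (abs(a - 0.5), a))


def confusion_counts(y_true: np.ndarray, y_pred: np.ndarray) -> ConfusionCounts:
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.size == 0:
        raise InputDataError("empty input")
    if y_true.shape != y_pred.shape:
        raise InputDataError("labels and predictions must have equal length")
    return ConfusionCounts(
        TP=int(np.sum((y_true == 1) & (y_pred == 1))),
        TN=int(np.sum((y_true == -1) & (y_pred == -1))),
        FP=int(np.sum((y_true == -1) & (y_pred == 1))),
        FN=int(np.sum((y_true == 1) & (y_pred == -1))),
    )


def compute_metrics(
    y_true: np.ndarray,
    y_pred: np.ndarray,
    decision_values: np.ndarray | None = None,
) -> dict[str, float]:
    """Confusion-derived metrics plus tie-averaged AUC.

    ACC = (TP+TN)/(TP+TN+FP+FN), SEN = TP/(TP+FN), SPEC = TN/(TN+FP),
    BAC = (SEN+SPEC)/2, PPV = TP/(TP+FP), NPV = TN/(TN+FN).  Undefined
    denominators are reported as NaN (missing), never as 0.  AUC is the
    rank statistic of the decision values with ties averaged, NaN when a
    class is absent or no scores are given.
    """
    c = confusion_counts(y_true, y_pred)

    def _ratio(num, den):
        return num / den if den > 0 else float("nan")

    sen = _ratio(c.TP, c.TP + c.FN)
    spec = _ratio(c.TN, c.TN + c.FP)
    metrics = {
        "ACC": _ratio(c.TP + c.TN, c.total),
        "SEN": sen,
        "SPEC": spec,
        "BAC": (sen + spec) / 2.0,
        "PPV": _ratio(c.TP, c.TP + c.FP),
        "NPV": _ratio(c.TN, c.TN + c.FN),
    }
    y_true = np.asarray(y_true)
    if decision_values is not None and np.unique(y_true).size == 2:
        metrics["AUC"] = float(roc_auc_score(y_true, np.asarray(decision_values)))
    else:
        metrics["AUC"] = float("nan")
    return metrics
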