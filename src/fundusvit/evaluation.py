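"""Localization and diagnostic metrics for the screening pipeline.

Covers the quantities a detection-plus-diagnosis study reports: box IoU
for localization quality; the confusion-matrix rates (accuracy,
sensitivity, specificity) for the binary glaucoma call; and threshold-free
ranking metrics (ROC with its AUC, precision-recall with average
precision) computed from the continuous cup-to-disc ratio as risk score.

Curve computation is delegated to scikit-learn, whose conventions match
the definitions used here: thresholds at unique score values with ties
grouped, trapezoidal ROC area, and step-function (non-interpolated)
average precision.  Undefined rates (empty denominators) are reported as
``None`` rather than silently coerced to 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np
from sklearn import metrics as _skm

from .geometry import BoundingBox

__all__ = ["EvalReport", "iou", "confusion_metrics", "roc_curve", "pr_curve"]


@dataclass
class EvalReport:
    """Container for all pipeline metrics; unavailable fields stay ``None``."""

    tp: int | None = None
    fp: int | None = None
    tn: int | None = None
    fn: int | None = None
    accuracy: float | None = None
    sensitivity: float | None = None
    specificity: float | None = None
    mean_iou: float | None = None
    roc_points: list[tuple[float, float]] | None = None
    auc: float | None = None
    pr_points: list[tuple[float, float]] | None = None
    average_precision: float | None = None

    def to_json(self, path: str | Path | None = None) -> str:
        doc = json.dumps(asdict(self), indent=2)
        if path is not None:
            Path(path).write_text(doc + "\n")
        return doc


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; 0 when disjoint or both degenerate."""
    ix = min(a.x_max, b.x_max) - max(a.x_min, b.x_min)
    iy = min(a.y_max, b.y_max) - max(a.y_min, b.y_min)
    inter = max(ix, 0.0) * max(iy, 0.0)
    union = a.area + b.area - inter
    return inter / union if union > 0 else 0.0


def _as_binary(values: Sequence[int], name: str) -> np.ndarray:
    arr = np.asarray(values)
    if not np.isin(arr, (0, 1)).all():
        raise ValueError(f"{name} must be binary 0/1 labels")
    return arr.astype(int)


def confusion_metrics(actual: Sequence[int], predicted: Sequence[int]) -> EvalReport:
    """Confusion counts and accuracy / sensitivity / specificity.

    ``actual`` and ``predicted`` are equal-length 0/1 sequences with 1 =
    glaucoma.  Sensitivity (specificity) is ``None`` when there are no
    positives (negatives) in ``actual``.
    """
    y, p = _as_binary(actual, "actual"), _as_binary(predicted, "predicted")
    if len(y) != len(p):
        raise ValueError(f"length mismatch: {len(y)} actual vs {len(p)} predicted")
    tp = int(((y == 1) & (p == 1)).sum())
    fp = int(((y == 0) & (p == 1)).sum())
    tn = int(((y == 0) & (p == 0)).sum())
    fn = int(((y == 1) & (p == 0)).sum())
    total = tp + fp + tn + fn
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        accuracy=(tp + tn) / total if total else None,
        sensitivity=tp / (tp + fn) if tp + fn else None,
        specificity=tn / (tn + fp) if tn + fp else None,
    )


def roc_curve(scores: Sequence[float], actual: Sequence[int],
              ) -> tuple[list[tuple[float, float]], float]:
    """ROC points ``(fpr, tpr)`` and trapezoidal AUC from a risk score.

    The natural score is the cup-to-disc ratio, but any monotone risk score
    works.  Raises ``ValueError`` when ``actual`` contains a single class
    (AUC undefined).
    """
    y = _as_binary(actual, "actual")
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("scores and actual must have equal length")
    if y.min() == y.max():
        raise ValueError("AUC undefined: actual labels contain a single class")
    fpr, tpr, _ = _skm.roc_curve(y, s)
    return list(zip(fpr.tolist(), tpr.tolist())), float(_skm.auc(fpr, tpr))


def pr_curve(scores: Sequence[float], actual: Sequence[int],
             ) -> tuple[list[tuple[float, float]], float]:
    """Precision-recall points ``(recall, precision)`` and average precision.

    AP is the step-function sum of precision times recall increments (no
    interpolation).  Requires at least one positive label.
    """
    y = _as_binary(actual, "actual")
    s = np.asarray(scores, dtype=float)
    if len(y) != len(s):
        raise ValueError("scores and actual must have equal length")
    if y.sum() == 0:
        raise ValueError("average precision undefined: no positive labels")
    precision, recall, _ = _skm.precision_recall_curve(y, s)
    ap = float(_skm.average_precision_score(y, s))
    return list(zip(recall.tolist(), precision.tolist())), ap


def curves_to_csv(points: list[tuple[float, float]], path: str | Path,
                  header: tuple[str, str]) -> None:
    """Write one curve as CSV, one point per row."""
    lines = [",".join(header)]
    lines += [f"{a},{b}" for a, b in points]
    Path(path).write_text("\n".join(lines) + "\n")
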