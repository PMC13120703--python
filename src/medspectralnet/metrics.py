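"""Confusion counts, accuracy, ROC/PR curves and their areas.

ROC points sweep thresholds over the distinct score values (equal scores are
processed together), TPR = TP/(TP+FN) against FPR = FP/(FP+TN); the ROC area
is trapezoidal over FPR, which equals the probability that a random positive
outranks a random negative (ties contribute half). The PR area uses the
step-wise average-precision sum rather than linear interpolation, which is
optimistically biased for PR curves. Multiclass evaluation is one-vs-rest on
the per-class probability columns, with accuracy = trace/total.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConfusionCounts:
    """Binary (or one-vs-rest) confusion quantities."""

    TP: int
    FP: int
    TN: int
    FN: int

    @property
    def total(self):
        return self.TP + self.FP + self.TN + self.FN


@dataclass
class Curve:
    points: np.ndarray     # ordered (x, y) pairs
    area: float
    kind: str              # "roc" or "pr"

    def to_dict(self):
        return {"kind": self.kind, "area": self.area, "points": self.points.tolist()}


def confusion_matrix(y_true, y_pred, num_classes):
    """K×K integer matrix; entry (i, j) counts true class i predicted as j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have the same length")
    for name, arr in (("y_true", y_true), ("y_pred", y_pred)):
        if arr.size and (arr.min() < 0 or arr.max() >= num_classes):
            raise ValueError(f"{name} contains labels outside [0, {num_classes})")
    mat = np.zeros((num_classes, num_classes), dtype=np.int64)
    np.add.at(mat, (y_true, y_pred), 1)
    return mat


def accuracy(confusion):
    """Proportion of correct predictions: trace/total."""
    confusion = np.asarray(confusion)
    total = confusion.sum()
    if total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(confusion) / total)


def binary_counts(y_true, y_pred):
    """ConfusionCounts for 0/1 labels and predictions."""
    m = confusion_matrix(y_true, y_pred, 2)
    return ConfusionCounts(TP=int(m[1, 1]), FP=int(m[0, 1]), TN=int(m[0, 0]), FN=int(m[1, 0]))


def _threshold_sweep(scores, labels):
    """Cumulative TP/FP over descending distinct score thresholds."""
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    # last index of each tie group
    distinct = np.where(np.diff(s))[0]
    idx = np.concatenate([distinct, [len(s) - 1]])
    tp = np.cumsum(y)[idx].astype(np.float64)
    fp = np.cumsum(1 - y)[idx].astype(np.float64)
    return tp, fp, float(y.sum()), float(len(y) - y.sum())


def roc_points(scores, labels):
    """ROC curve over all thresholds, endpoints (0,0) and (1,1) included."""
    labels = np.asarray(labels)
    if len(set(labels.tolist())) < 2:
        raise ValueError("ROC/AUC undefined: labels contain a single class")
    tp, fp, P, N = _threshold_sweep(scores, labels)
    tpr = np.concatenate([[0.0], tp / P])
    fpr = np.concatenate([[0.0], fp / N])
    points = np.column_stack([fpr, tpr])
    curve = Curve(points=points, area=0.0, kind="roc")
    curve.area = curve_area(curve)
    return curve


def pr_points(scores, labels):
    """Precision-recall curve in descending score order."""
    labels = np.asarray(labels)
    if labels.sum() == 0:
        raise ValueError("PR curve undefined: no positive labels")
    tp, fp, P, _ = _threshold_sweep(scores, labels)
    precision = tp / (tp + fp)
    recall = tp / P
    points = np.column_stack([recall, precision])
    curve = Curve(points=points, area=0.0, kind="pr")
    curve.area = curve_area(curve)
    return curve


def curve_area(curve: Curve):
    """Area under a curve: trapezoidal over FPR (ROC) or step-wise AP (PR)."""
    pts = np.asarray(curve.points, dtype=np.float64)
    if len(pts) < 2 and curve.kind == "roc":
        raise ValueError("need at least two points")
    x, y = pts[:, 0], pts[:, 1]
    if curve.kind == "roc":
        if np.any(np.diff(x) < 0):
            raise ValueError("ROC points must be ordered by nondecreasing FPR")
        return float(np.trapezoid(y, x))
    # PR: sum of precision * recall increments (average precision)
    prev_r = 0.0
    area = 0.0
    for r, p in pts:
        if r < prev_r:
            raise ValueError("PR points must be ordered by nondecreasing recall")
        area += (r - prev_r) * p
        prev_r = r
    return float(area)


def one_vs_rest(prob_matrix, labels, kind="roc"):
    """Per-class curves scored one column vs the binarized labels.

    Returns (curves, areas, macro) where curves[c] / areas[c] is None for a
    class absent from the labels (excluded from the macro average).
    """
    prob_matrix = np.asarray(prob_matrix, dtype=np.float64)
    labels = np.asarray(labels)
    if not np.allclose(prob_matrix.sum(axis=1), 1.0, atol=1e-5):
        raise ValueError("probability rows must sum to 1")
    K = prob_matrix.shape[1]
    make = roc_points if kind == "roc" else pr_points
    curves, areas = [], []
    for c in range(K):
        binary = (labels == c).astype(np.int64)
        if binary.sum() == 0 or binary.sum() == len(binary):
            curves.append(None)
            areas.append(None)
            continue
        curve = make(prob_matrix[:, c], binary)
        curves.append(curve)
        areas.append(curve.area)
    defined = [a for a in areas if a is not None]
    macro = float(np.mean(defined)) if defined else float("nan")
    return curves, areas, macro


def save_curves_json(path, curves, areas, macro):
    payload = {
        "macro_area": macro,
        "per_class": [
            None if c is None else c.to_dict() for c in curves
        ],
        "areas": areas,
    }
    with open(path, "w") as fh:
        json.dump(payload, fh)
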