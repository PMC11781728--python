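"""Confusion-matrix metrics, nested cross-validation plans, and
length-stratified analysis.

Metrics are computed from the confusion matrix itself (rows = true class,
columns = predicted class): accuracy, per-class and macro precision /
recall / F1 with the 0/0 -> 0 convention, and the Matthews correlation
coefficient.  For more than two classes the MCC uses the covariance
(R_k) generalisation

    MCC = (c*s - sum_k p_k t_k) /
          sqrt((s^2 - sum_k p_k^2) (s^2 - sum_k t_k^2))

with c = trace, s = total count, t_k / p_k = true / predicted marginals;
at C = 2 this reduces exactly to the familiar
(TP*TN - FP*FN) / sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)) form.  A zero
denominator returns 0.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from sklearn.model_selection import KFold, StratifiedKFold


def confusion_matrix(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int) -> np.ndarray:
    """C x C count matrix; entry (i, j) counts items with true i, predicted j."""
    y_true = np.asarray(y_true, dtype=np.int64)
    y_pred = np.asarray(y_pred, dtype=np.int64)
    if y_true.shape != y_pred.shape:
        raise ValueError("y_true and y_pred must have equal length")
    for name, y in (("y_true", y_true), ("y_pred", y_pred)):
        if y.size and (y.min() < 0 or y.max() >= n_classes):
            raise ValueError(f"{name} contains labels outside [0, {n_classes})")
    cm = np.zeros((n_classes, n_classes), dtype=np.int64)
    np.add.at(cm, (y_true, y_pred), 1)
    return cm


def mcc(cm: np.ndarray) -> float:
    """Matthews correlation coefficient from a confusion matrix.

    Counts are integers, so the numerator and the squared denominator are
    computed in exact integer arithmetic; perfect agreement is exactly 1.
    """
    import math

    cm = np.asarray(cm)
    if np.issubdtype(cm.dtype, np.floating):
        cm = np.rint(cm).astype(np.int64)
    c = int(np.trace(cm))
    s = int(cm.sum())
    t = [int(x) for x in cm.sum(axis=1)]  # true-class marginals
    p = [int(x) for x in cm.sum(axis=0)]  # predicted-class marginals
    num = c * s - sum(a * b for a, b in zip(t, p))
    den2 = (s * s - sum(a * a for a in p)) * (s * s - sum(a * a for a in t))
    if den2 == 0:
        return 0.0
    root = math.isqrt(den2)
    den = float(root) if root * root == den2 else math.sqrt(den2)
    return float(num / den)


@dataclass
class MetricsReport:
    """Confusion matrix plus the derived classification metrics."""

    confusion: np.ndarray
    accuracy: float
    precision: np.ndarray        # per class
    recall: np.ndarray
    f1: np.ndarray
    macro_precision: float
    macro_recall: float
    macro_f1: float
    mcc: float

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "mcc": self.mcc,
        }

    def to_json(self, **kwargs) -> str:
        return json.dumps(self.to_dict(), **kwargs)

    def summary_row(self) -> dict:
        """The headline row: accuracy, macro precision/recall/F1, MCC."""
        return {"accuracy": self.accuracy, "precision": self.macro_precision,
                "recall": self.macro_recall, "macro_f1": self.macro_f1, "mcc": self.mcc}


def classification_metrics(cm: np.ndarray) -> MetricsReport:
    """All metrics from a confusion matrix, with 0/0 cells defined as 0."""
    cm = np.asarray(cm)
    if cm.ndim != 2 or cm.shape[0] != cm.shape[1] or cm.shape[0] == 0:
        raise ValueError("confusion matrix must be square and non-empty")
    if (cm < 0).any():
        raise ValueError("confusion matrix entries must be non-negative")
    total = cm.sum()
    tp = np.diag(cm).astype(np.float64)
    pred = cm.sum(axis=0).astype(np.float64)
    true = cm.sum(axis=1).astype(np.float64)
    precision = np.divide(tp, pred, out=np.zeros_like(tp), where=pred > 0)
    recall = np.divide(tp, true, out=np.zeros_like(tp), where=true > 0)
    pr = precision + recall
    f1 = np.divide(2 * precision * recall, pr, out=np.zeros_like(tp), where=pr > 0)
    return MetricsReport(
        confusion=np.asarray(cm, dtype=np.int64),
        accuracy=float(tp.sum() / total) if total > 0 else 0.0,
        precision=precision,
        recall=recall,
        f1=f1,
        macro_precision=float(precision.mean()),
        macro_recall=float(recall.mean()),
        macro_f1=float(f1.mean()),
        mcc=mcc(cm),
    )


def evaluate_predictions(y_true: Sequence[int], y_pred: Sequence[int], n_classes: int) -> MetricsReport:
    return classification_metrics(confusion_matrix(y_true, y_pred, n_classes))


def reports_to_csv(rows: dict[str, MetricsReport], path) -> None:
    """Write one summary row per named report (accuracy, P, R, macro F1, MCC)."""
    import pandas as pd

    df = pd.DataFrame({name: r.summary_row() for name, r in rows.items()}).T
    df.index.name = "model"
    df.to_csv(path)


# ---------------------------------------------------------------------------
# Nested cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CVPlan:
    """A 5x3 (by default) nested cross-validation plan over item indices.

    ``outer[f]`` is the (train_idx, test_idx) split of fold f; ``inner[f]``
    lists (train_idx, dev_idx) splits of the outer-train items.  All index
    arrays refer to positions in the original dataset.
    """

    outer: list[tuple[np.ndarray, np.ndarray]]
    inner: list[list[tuple[np.ndarray, np.ndarray]]]
    seed: int

    def triples(self) -> list[tuple[int, int, np.ndarray, np.ndarray, np.ndarray]]:
        """Enumerate every (outer_fold, inner_fold, train, dev, test) triple;
        with 5 outer and 3 inner folds this is the 15 experiments run for a
        single setting."""
        out = []
        for of, (_, test_idx) in enumerate(self.outer):
            for inf, (train_idx, dev_idx) in enumerate(self.inner[of]):
                out.append((of, inf, train_idx, dev_idx, test_idx))
        return out


def nested_cv_splits(labels: Sequence[int], outer: int = 5, inner: int = 3,
                     seed: int = 0, stratify: bool = True) -> CVPlan:
    """Build a stratified (by default) nested CV plan.

    Outer folds partition all items into ``outer`` near-equal test sets;
    within each outer-train set, ``inner`` folds partition the items into
    train/dev splits.  Deterministic given ``seed``.
    """
    labels = np.asarray(labels)
    n = len(labels)
    if n < outer * inner:
        raise ValueError(f"need at least {outer * inner} items, got {n}")
    idx = np.arange(n)

    def splitter(k, rs):
        if stratify:
            return StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        return KFold(n_splits=k, shuffle=True, random_state=rs)

    outer_splits = [(idx[tr], idx[te])
                    for tr, te in splitter(outer, seed).split(idx, labels)]
    inner_splits = []
    for f, (tr, _te) in enumerate(outer_splits):
        subs = [(tr[i], tr[j])
                for i, j in splitter(inner, seed + 1 + f).split(tr, labels[tr])]
        inner_splits.append(subs)
    return CVPlan(outer=outer_splits, inner=inner_splits, seed=seed)


# ---------------------------------------------------------------------------
# Length stratification
# ---------------------------------------------------------------------------

LENGTH_BINS = ("short", "middle", "long")


def length_stratify(sequence_lengths: Sequence[int]) -> np.ndarray:
    """Assign each length to 'short' (< Q1), 'middle' ([Q1, Q3]) or 'long'
    (> Q3), with quartiles computed by linear interpolation."""
    lengths = np.asarray(sequence_lengths, dtype=np.float64)
    if lengths.size < 4:
        raise ValueError("need at least 4 lengths to form quartile bins")
    q1, q3 = np.percentile(lengths, [25, 75])
    bins = np.full(lengths.shape, "middle", dtype=object)
    bins[lengths < q1] = "short"
    bins[lengths > q3] = "long"
    return bins


def metrics_by_length(y_true: Sequence[int], y_pred: Sequence[int],
                      sequence_lengths: Sequence[int], n_classes: int) -> dict[str, MetricsReport]:
    """One MetricsReport per length bin (bins that occur in the data)."""
    bins = length_stratify(sequence_lengths)
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    out = {}
    for name in LENGTH_BINS:
        sel = bins == name
        if sel.any():
            out[name] = evaluate_predictions(y_true[sel], y_pred[sel], n_classes)
    return out
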