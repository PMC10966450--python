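"""Binary-classification metrics, ROC curves, CV pooling, fill-rate diagnostics."""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
from sklearn.metrics import roc_curve

from .tensorize import VoxelGrid


class EvaluationError(ValueError):
    pass


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fn: int
    fp: int
    tn: int

    def __post_init__(self):
        if min(self.tp, self.fn, self.fp, self.tn) < 0:
            raise EvaluationError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fn + self.fp + self.tn


@dataclass
class MetricReport:
    acc: float
    auc: float
    precision: float  # nan when undefined (no positive predictions)
    recall: float
    confusion: ConfusionCounts
    roc_points: list = field(default_factory=list)
    per_fold_acc: list = field(default_factory=list)
    acc_mean_abs_deviation: float | None = None
    acc_std: float | None = None

    def to_json(self) -> str:
        d = {
            "acc": self.acc, "auc": self.auc,
            "precision": None if math.isnan(self.precision) else self.precision,
            "recall": self.recall,
            "confusion": {"tp": self.confusion.tp, "fn": self.confusion.fn,
                          "fp": self.confusion.fp, "tn": self.confusion.tn},
            "per_fold_acc": self.per_fold_acc,
            "acc_mean_abs_deviation": self.acc_mean_abs_deviation,
            "acc_std": self.acc_std,
        }
        return json.dumps(d, indent=2)

    def roc_tsv(self) -> str:
        lines = ["fpr\ttpr\tthreshold"]
        for fpr, tpr, thr in self.roc_points:
            lines.append(f"{fpr:.6f}\t{tpr:.6f}\t{thr:.6f}")
        return "\n".join(lines) + "\n"


def confusion_at_threshold(labels, scores, threshold: float = 0.5
                           ) -> ConfusionCounts:
    """Binarize scores (>= threshold predicts positive) and count outcomes."""
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.size == 0:
        raise EvaluationError("empty prediction set")
    if labels.shape != scores.shape:
        raise EvaluationError("labels and scores must have equal length")
    pred = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        tp=int((pred & pos).sum()),
        fn=int((~pred & pos).sum()),
        fp=int((pred & ~pos).sum()),
        tn=int((~pred & ~pos).sum()),
    )


def metrics_from_confusion(c: ConfusionCounts) -> tuple[float, float, float]:
    """(accuracy, precision, recall); precision is nan if never predicted
    positive, recall is 0 for an all-negative truth."""
    if c.total == 0:
        raise EvaluationError("empty confusion matrix")
    acc = (c.tp + c.tn) / c.total
    precision = c.tp / (c.tp + c.fp) if (c.tp + c.fp) else float("nan")
    recall = c.tp / (c.tp + c.fn) if (c.tp + c.fn) else 0.0
    return acc, precision, recall


def roc_auc(labels, scores) -> tuple[float, list]:
    """Trapezoidal AUC over the empirical ROC.

    Equivalent to the Mann-Whitney U statistic (ties rank-averaged).
    Returns (auc, [(fpr, tpr, threshold), ...]).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if len(set(labels.tolist())) < 2:
        raise EvaluationError("ROC requires both classes present")
    fpr, tpr, thr = roc_curve(labels, scores)
    auc = float(np.trapezoid(tpr, fpr))
    points = list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))
    return auc, points


def aggregate_cv(per_fold_predictions, threshold: float = 0.5) -> MetricReport:
    """Pool fold predictions and compute metrics on the pooled set.

    ``per_fold_predictions`` is a sequence of (pair_keys, labels, scores)
    triples, one per fold, covering disjoint pairs.  Metrics are computed
    on the pooled predictions (not averaged over folds); the per-fold
    accuracy spread is reported as mean absolute deviation and (population)
    standard deviation.
    """
    seen: set = set()
    labels, scores, fold_accs = [], [], []
    for keys, fold_labels, fold_scores in per_fold_predictions:
        keys = list(keys)
        overlap = seen & set(keys)
        if overlap:
            raise EvaluationError(f"pairs appear in multiple folds: {sorted(overlap)[:5]}")
        seen.update(keys)
        fold_labels = np.asarray(fold_labels, dtype=int)
        fold_scores = np.asarray(fold_scores, dtype=float)
        labels.append(fold_labels)
        scores.append(fold_scores)
        c = confusion_at_threshold(fold_labels, fold_scores, threshold)
        fold_accs.append((c.tp + c.tn) / c.total)

    labels = np.concatenate(labels)
    scores = np.concatenate(scores)
    conf = confusion_at_threshold(labels, scores, threshold)
    acc, precision, recall = metrics_from_confusion(conf)
    try:
        auc, points = roc_auc(labels, scores)
    except EvaluationError:
        auc, points = float("nan"), []
    fold_accs_arr = np.asarray(fold_accs)
    return MetricReport(
        acc=acc, auc=auc, precision=precision, recall=recall, confusion=conf,
        roc_points=points, per_fold_acc=fold_accs,
        acc_mean_abs_deviation=float(
            np.abs(fold_accs_arr - fold_accs_arr.mean()).mean()),
        acc_std=float(fold_accs_arr.std()),
    )


def fill_rate(g: VoxelGrid, region: str = "whole",
              per_channel: bool = False) -> float:
    """Fraction of non-zero cells in a grid region.

    A cell counts as filled if any channel is non-zero (set
    ``per_channel=True`` to count channel entries individually).  The
    ``central`` region is the centered half-side subgrid (32^3 cells for a
    64-cell grid), where the interface sits by construction.
    """
    values = g.values
    if region == "central":
        n = values.shape[0]
        lo, hi = n // 4, n // 4 + n // 2
        values = values[lo:hi, lo:hi, lo:hi, :]
    elif region != "whole":
        raise EvaluationError(f"unknown region {region!r}")
    if per_channel:
        return float((values != 0).mean())
    return float((values != 0).any(axis=-1).mean())
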