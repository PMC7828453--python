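"""Multiclass evaluation: confusion matrix, accuracy, macro-F1, micro-OVR ROC,
and weight/threshold parameter counting.

Class order everywhere is the frozen 9-mode order (or any explicit label list
for node-level k-way problems).  F1 is macro-averaged (the recording
protocol allots equal time per mode, so classes are balanced by design); the
ROC curve is
micro-averaged one-vs-rest over all (instance, class) score pairs with AUC by
the trapezoid rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .data import MODES
from .ibpnn import param_count


@dataclass
class ConfusionMatrix:
    """Integer counts, rows = true class, columns = predicted class."""

    counts: np.ndarray
    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts)
        k = len(self.labels)
        if self.counts.shape != (k, k):
            raise ValueError("confusion matrix shape disagrees with label count")
        if np.any(self.counts < 0):
            raise ValueError("negative count")

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def proportional(self) -> np.ndarray:
        """Row-normalized view; all-zero rows stay zero."""
        sums = self.counts.sum(axis=1, keepdims=True)
        return np.divide(self.counts, sums, out=np.zeros(self.counts.shape), where=sums > 0)

    def to_csv(self, path: str | Path) -> None:
        header = "true\\pred," + ",".join(self.labels)
        rows = [f"{lab}," + ",".join(str(int(v)) for v in row) for lab, row in zip(self.labels, self.counts)]
        Path(path).write_text("\n".join([header, *rows]) + "\n")


def confusion(
    true_labels: Sequence[str], pred_labels: Sequence[str], labels: Sequence[str] = MODES
) -> ConfusionMatrix:
    true_labels = [str(v) for v in true_labels]
    pred_labels = [str(v) for v in pred_labels]
    if len(true_labels) != len(pred_labels):
        raise ValueError("true and predicted label sequences differ in length")
    index = {lab: i for i, lab in enumerate(labels)}
    bad = [v for v in (*true_labels, *pred_labels) if v not in index]
    if bad:
        raise ValueError(f"label {bad[0]!r} not in class list {list(labels)}")
    counts = np.zeros((len(labels), len(labels)), dtype=int)
    for t, p in zip(true_labels, pred_labels):
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(counts, tuple(labels))


def accuracy(cm: ConfusionMatrix) -> float:
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    return float(np.trace(cm.counts)) / cm.total


def per_class_precision_recall(cm: ConfusionMatrix) -> tuple[np.ndarray, np.ndarray]:
    tp = np.diag(cm.counts).astype(float)
    pred_tot = cm.counts.sum(axis=0).astype(float)
    true_tot = cm.counts.sum(axis=1).astype(float)
    precision = np.divide(tp, pred_tot, out=np.zeros_like(tp), where=pred_tot > 0)
    recall = np.divide(tp, true_tot, out=np.zeros_like(tp), where=true_tot > 0)
    return precision, recall


def macro_f1(cm: ConfusionMatrix) -> float:
    """Unweighted mean of per-class F1; a class with P + R = 0 scores 0."""
    if cm.total == 0:
        raise ValueError("empty confusion matrix")
    p, r = per_class_precision_recall(cm)
    denom = p + r
    f1 = np.divide(2 * p * r, denom, out=np.zeros_like(p), where=denom > 0)
    return float(f1.mean())


def roc_curve(
    scores: np.ndarray, true_labels: Sequence[str], labels: Sequence[str] = MODES
) -> tuple[np.ndarray, np.ndarray, float]:
    """Micro-averaged one-vs-rest ROC by threshold sweep.

    ``scores`` is (N, k) network outputs in [0, 1]; every (instance, class)
    pair becomes one binary decision. Returns (fpr, tpr, auc); the curve is
    anchored at (0, 0) and (1, 1).
    """
    scores = np.asarray(scores, dtype=float)
    true_labels = [str(v) for v in true_labels]
    index = {lab: i for i, lab in enumerate(labels)}
    if len(set(true_labels)) < 2:
        raise ValueError("ROC needs at least two classes present")
    y = np.zeros(scores.shape)
    for i, lab in enumerate(true_labels):
        y[i, index[lab]] = 1.0
    s = scores.ravel()
    y = y.ravel()
    order = np.argsort(-s, kind="stable")
    s, y = s[order], y[order]
    tp = np.cumsum(y)
    fp = np.cumsum(1.0 - y)
    # collapse ties: keep the last point of each distinct threshold
    distinct = np.r_[np.diff(s) != 0, True]
    tp, fp = tp[distinct], fp[distinct]
    P, N = tp[-1], fp[-1]
    tpr = np.r_[0.0, tp / P, 1.0]
    fpr = np.r_[0.0, fp / N, 1.0]
    auc = float(np.trapezoid(tpr, fpr))
    return fpr, tpr, auc


@dataclass
class MetricsReport:
    """The evaluation surface of one classifier on one test set."""

    cm: ConfusionMatrix
    accuracy: float
    macro_f1: float
    precision: np.ndarray
    recall: np.ndarray
    roc: tuple[np.ndarray, np.ndarray] | None = None
    auc: float | None = None

    def to_dict(self) -> dict:
        d = {
            "accuracy": self.accuracy,
            "macro_f1": self.macro_f1,
            "labels": list(self.cm.labels),
            "per_class_precision": self.precision.tolist(),
            "per_class_recall": self.recall.tolist(),
        }
        if self.auc is not None:
            d["auc"] = self.auc
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def evaluate_predictions(
    true_labels: Sequence[str],
    pred_labels: Sequence[str],
    labels: Sequence[str] = MODES,
    scores: np.ndarray | None = None,
) -> MetricsReport:
    cm = confusion(true_labels, pred_labels, labels)
    p, r = per_class_precision_recall(cm)
    report = MetricsReport(cm, accuracy(cm), macro_f1(cm), p, r)
    if scores is not None:
        fpr, tpr, auc = roc_curve(scores, true_labels, labels)
        report.roc = (fpr, tpr)
        report.auc = auc
    return report


def roc_to_csv(fpr: np.ndarray, tpr: np.ndarray, path: str | Path) -> None:
    lines = ["fpr,tpr"] + [f"{a!r},{b!r}" for a, b in zip(fpr, tpr)]
    Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# Parameter counting


@dataclass
class ParamCountReport:
    """Weights-plus-thresholds totals for a set of networks, optionally
    against a baseline set (reduction = 1 - optimized/baseline)."""

    archs: list[tuple[int, int, int]]
    per_network: list[int]
    total: int
    baseline_total: int | None = None
    reduction: float | None = None

    def to_dict(self) -> dict:
        d = {
            "architectures": [list(a) for a in self.archs],
            "per_network": self.per_network,
            "total": self.total,
        }
        if self.baseline_total is not None:
            d["baseline_total"] = self.baseline_total
            d["reduction"] = self.reduction
        return d


def count_params(
    archs: Sequence[tuple[int, int, int]],
    baseline_archs: Sequence[tuple[int, int, int]] | None = None,
) -> ParamCountReport:
    """Per-network and total weight/threshold counts, m(n+1) + l(m+1) each."""
    archs = [tuple(int(v) for v in a) for a in archs]
    if not archs:
        raise ValueError("no architectures given")
    if any(v < 1 for a in archs for v in a):
        raise ValueError("layer sizes must be positive")
    per = [param_count(*a) for a in archs]
    report = ParamCountReport(archs, per, sum(per))
    if baseline_archs is not None:
        base = count_params(baseline_archs)
        report.baseline_total = base.total
        report.reduction = 1.0 - report.total / base.total
    return report
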