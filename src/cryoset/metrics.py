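"""Voxel-wise evaluation of predicted label volumes.

Predictions arrive as a per-voxel probability vector over N classes
(class 0 = background/"nothing").  :func:`discretize` turns them into
hard labels: a voxel gets the argmax non-background class if that
probability exceeds the threshold (0.8 for the secondary-structure
setting; 0.4 for the nucleic-acid atom-group setting), otherwise
background.  :func:`confusion` tallies one-vs-rest TP/FP/FN/TN per
label, and :func:`score_metrics` derives

    accuracy  = (TP + TN) / (TP + TN + FP + FN)
    precision = TP / (TP + FP)
    recall    = TP / (TP + FN)
    F1        = 2 * precision * recall / (precision + recall)

per label, plus a micro-average over the non-background labels and the
overall multi-class voxel agreement.  Zero denominators yield 0 with
an explicit ``undefined`` flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

import numpy as np

from .errors import UsageError
from .labeling import LabelVolume

__all__ = [
    "PredictionVolume",
    "ConfusionTable",
    "LabelMetrics",
    "discretize",
    "confusion",
    "score_metrics",
]


@dataclass
class PredictionVolume:
    """Per-voxel class probabilities, shaped (classes, nx, ny, nz)."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        self.probs = np.asarray(self.probs, dtype=np.float64)
        if self.probs.ndim != 4:
            raise UsageError("probabilities must be shaped (classes, x, y, z)")
        if (self.probs < 0).any():
            raise UsageError("probabilities must be non-negative")
        sums = self.probs.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise UsageError("per-voxel probabilities must sum to 1 (tol 1e-6)")

    @property
    def n_classes(self) -> int:
        return self.probs.shape[0]


def discretize(pred: PredictionVolume, threshold: float = 0.8) -> LabelVolume:
    """Hard labels from probabilities.

    Among non-background classes with probability strictly above
    *threshold* the argmax wins (exact ties -> the lowest class index);
    if none exceeds the threshold the voxel is background (0).
    """
    if not 0.0 < threshold < 1.0:
        raise UsageError("threshold must lie in (0, 1)")
    fg = pred.probs[1:]
    best = np.argmax(fg, axis=0) + 1  # argmax picks the lowest index on ties
    best_p = np.max(fg, axis=0)
    labels = np.where(best_p > threshold, best, 0).astype(np.int32)
    return LabelVolume(labels, voxel_size=(1.0, 1.0, 1.0), origin=(0.0, 0.0, 0.0))


@dataclass
class ConfusionTable:
    """One-vs-rest voxel counts per label; conserves the voxel total."""

    counts: dict[int, tuple[int, int, int, int]]  # label -> (TP, FP, FN, TN)
    total: int

    def __post_init__(self) -> None:
        for label, (tp, fp, fn, tn) in self.counts.items():
            if min(tp, fp, fn, tn) < 0 or tp + fp + fn + tn != self.total:
                raise UsageError(f"label {label}: counts do not sum to the voxel total")


def confusion(
    pred: LabelVolume | np.ndarray,
    truth: LabelVolume | np.ndarray,
    labels: Iterable[int] | None = None,
) -> ConfusionTable:
    """One-vs-rest confusion counts for every label (background included)."""
    p = pred.grid if isinstance(pred, LabelVolume) else np.asarray(pred)
    t = truth.grid if isinstance(truth, LabelVolume) else np.asarray(truth)
    if p.shape != t.shape:
        raise UsageError(f"shape mismatch {p.shape} vs {t.shape}")
    if labels is None:
        labels = np.union1d(np.unique(p), np.unique(t)).tolist()
    total = p.size
    counts = {}
    for k in labels:
        tp = int(((p == k) & (t == k)).sum())
        fp = int(((p == k) & (t != k)).sum())
        fn = int(((p != k) & (t == k)).sum())
        counts[int(k)] = (tp, fp, fn, total - tp - fp - fn)
    return ConfusionTable(counts, total)


@dataclass
class LabelMetrics:
    accuracy: float
    precision: float
    recall: float
    f1: float
    undefined: set[str] = field(default_factory=set)


def _prf(tp: int, fp: int, fn: int, tn: int) -> LabelMetrics:
    undefined: set[str] = set()
    acc = (tp + tn) / (tp + tn + fp + fn)
    prec = rec = f1 = 0.0
    if tp + fp:
        prec = tp / (tp + fp)
    else:
        undefined.add("precision")
    if tp + fn:
        rec = tp / (tp + fn)
    else:
        undefined.add("recall")
    if prec + rec:
        f1 = 2 * prec * rec / (prec + rec)
    else:
        undefined.add("f1")
    return LabelMetrics(acc, prec, rec, f1, undefined)


def score_metrics(ct: ConfusionTable) -> dict:
    """Per-label and aggregate accuracy / precision / recall / F1.

    The aggregate precision/recall/F1 micro-average the non-background
    labels; the overall accuracy is the multi-class voxel agreement.
    """
    per_label = {k: _prf(*ct.counts[k]) for k in sorted(ct.counts)}
    fg = [k for k in ct.counts if k != 0]
    tp = sum(ct.counts[k][0] for k in fg)
    fp = sum(ct.counts[k][1] for k in fg)
    fn = sum(ct.counts[k][2] for k in fg)
    micro = _prf(tp, fp, fn, ct.total - tp - fp - fn)
    # multi-class agreement: every voxel's predicted label equals truth
    # iff it is a one-vs-rest TP for its true label
    agree = sum(ct.counts[k][0] for k in ct.counts)
    overall_accuracy = agree / ct.total if 0 in ct.counts else micro.accuracy
    return {
        "per_label": per_label,
        "precision": micro.precision,
        "recall": micro.recall,
        "f1": micro.f1,
        "accuracy": overall_accuracy,
        "undefined": micro.undefined,
    }
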