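"""Segmentation metrics: Dice, mean IoU, sensitivity, accuracy, AUC.

Conventions for degenerate counts: overlap ratios whose denominator is zero
(e.g. Dice when neither mask has foreground) are defined as 1 — perfect
agreement on absence. AUC is undefined (``None``) when the truth contains a
single class.

``evaluate_set`` micro-averages by pooling confusion counts across pairs
(macro-averaging of per-pair reports is also available).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata


@dataclass(frozen=True)
class ConfusionCounts:
    tp: int
    fp: int
    tn: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.tn, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.fp + self.tn + self.fn

    def __add__(self, other: "ConfusionCounts") -> "ConfusionCounts":
        return ConfusionCounts(self.tp + other.tp, self.fp + other.fp,
                               self.tn + other.tn, self.fn + other.fn)


@dataclass
class MetricsReport:
    dsc: float
    miou: float
    sen: float
    acc: float
    auc: float | None = None
    foreground_iou: float | None = None

    def to_dict(self) -> dict:
        return {k: v for k, v in vars(self).items()}


def _binary(arr, name):
    arr = np.asarray(arr)
    vals = np.unique(arr)
    if not np.all(np.isin(vals, (0, 1))):
        raise ValueError(f"{name} must be binary (0/1), found values {vals[:5]}")
    return arr.astype(bool)


def confusion(pred, truth) -> ConfusionCounts:
    """Exact pixel confusion counts between two binary grids."""
    pred, truth = _binary(pred, "pred"), _binary(truth, "truth")
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: pred {pred.shape} vs truth {truth.shape}")
    tp = int(np.count_nonzero(pred & truth))
    fp = int(np.count_nonzero(pred & ~truth))
    fn = int(np.count_nonzero(~pred & truth))
    tn = pred.size - tp - fp - fn
    return ConfusionCounts(tp=tp, fp=fp, tn=tn, fn=fn)


def _ratio(num, den) -> float:
    return 1.0 if den == 0 else num / den


def dsc(counts: ConfusionCounts) -> float:
    """Dice similarity coefficient 2TP / (2TP + FP + FN)."""
    return _ratio(2 * counts.tp, 2 * counts.tp + counts.fp + counts.fn)


def sen(counts: ConfusionCounts) -> float:
    """Sensitivity (recall of the vessel class) TP / (TP + FN)."""
    return _ratio(counts.tp, counts.tp + counts.fn)


def acc(counts: ConfusionCounts) -> float:
    """Pixel accuracy (TP + TN) / total."""
    return _ratio(counts.tp + counts.tn, counts.total)


def iou_foreground(counts: ConfusionCounts) -> float:
    return _ratio(counts.tp, counts.tp + counts.fp + counts.fn)


def iou_background(counts: ConfusionCounts) -> float:
    return _ratio(counts.tn, counts.tn + counts.fp + counts.fn)


def miou(counts: ConfusionCounts) -> float:
    """Mean IoU over the two classes (vessel and background)."""
    return 0.5 * (iou_foreground(counts) + iou_background(counts))


def auc(prob, truth) -> float | None:
    """Rank-based AUC: P(random positive outranks random negative), ties 1/2.

    Equals trapezoidal ROC integration. Returns None if the truth is
    single-class.
    """
    prob = np.asarray(prob, dtype=float).ravel()
    truth = _binary(truth, "truth").ravel()
    n_pos = int(truth.sum())
    n_neg = truth.size - n_pos
    if n_pos == 0 or n_neg == 0:
        return None
    ranks = rankdata(prob)                     # average ranks resolve ties as 1/2
    r_pos = ranks[truth].sum()
    u = r_pos - n_pos * (n_pos + 1) / 2.0
    return float(u / (n_pos * n_neg))


def report_from_counts(counts: ConfusionCounts, auc_value=None) -> MetricsReport:
    return MetricsReport(dsc=dsc(counts), miou=miou(counts), sen=sen(counts),
                         acc=acc(counts), auc=auc_value,
                         foreground_iou=iou_foreground(counts))


def evaluate_pair(prob, truth, threshold: float = 0.5) -> MetricsReport:
    """Binarize one probability map and compute the full report."""
    counts = confusion(np.asarray(prob) >= threshold, truth)
    return report_from_counts(counts, auc_value=auc(prob, truth))


def evaluate_set(pairs, threshold: float = 0.5, average: str = "micro") -> MetricsReport:
    """Metrics over (probability, truth) pairs.

    micro: pool confusion counts and probabilities over all pairs (default).
    macro: average the per-pair reports.
    """
    pairs = list(pairs)
    if not pairs:
        raise ValueError("evaluate_set needs at least one (prob, truth) pair")
    if not (0.0 < threshold < 1.0):
        raise ValueError("threshold must lie in (0, 1)")
    if average == "micro":
        total = ConfusionCounts(0, 0, 0, 0)
        for prob, truth in pairs:
            total = total + confusion(np.asarray(prob) >= threshold, truth)
        all_prob = np.concatenate([np.asarray(p, dtype=float).ravel() for p, _ in pairs])
        all_truth = np.concatenate([np.asarray(t).ravel() for _, t in pairs])
        return report_from_counts(total, auc_value=auc(all_prob, all_truth))
    if average == "macro":
        reports = [evaluate_pair(p, t, threshold) for p, t in pairs]
        aucs = [r.auc for r in reports if r.auc is not None]
        return MetricsReport(
            dsc=float(np.mean([r.dsc for r in reports])),
            miou=float(np.mean([r.miou for r in reports])),
            sen=float(np.mean([r.sen for r in reports])),
            acc=float(np.mean([r.acc for r in reports])),
            auc=float(np.mean(aucs)) if aucs else None,
            foreground_iou=float(np.mean([r.foreground_iou for r in reports])),
        )
    raise ValueError(f"unknown averaging mode {average!r}")


def best_threshold_baseline(pairs, n_thresholds: int = 101):
    """Best global-intensity-threshold Dice over a set of (image, truth) pairs.

    Scans thresholds on [0, 1], binarizing every image at the same global
    cut, and returns (best_threshold, best_micro_dice).  This is the trivial
    baseline a learned segmenter must beat.
    """
    pairs = [(np.asarray(im, dtype=float), np.asarray(t)) for im, t in pairs]
    best_t, best_d = 0.5, -1.0
    for t in np.linspace(0.0, 1.0, n_thresholds):
        total = ConfusionCounts(0, 0, 0, 0)
        for im, truth in pairs:
            total = total + confusion(im >= t, truth)
        d = dsc(total)
        if d > best_d:
            best_t, best_d = float(t), d
    return best_t, best_d
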