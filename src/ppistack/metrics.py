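"""Evaluation metrics for imbalanced binary site prediction.

Threshold metrics (accuracy, precision, recall, F1, Matthews correlation)
are computed from the confusion counts with the convention that a score
exactly at the threshold is a positive call, and that any metric with a
zero denominator is reported as 0 rather than NaN so that degenerate runs
remain comparable. AUROC uses the rank (Mann-Whitney) formulation with
ties counted half; AUPRC is average precision (stepwise integration of the
precision-recall curve, no interpolation).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata

__all__ = [
    "ConfusionCounts",
    "confusion_from_scores",
    "scalar_metrics",
    "auroc",
    "auprc",
    "per_class_accuracy",
]


@dataclass
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


def _check_pair(labels, scores):
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ValueError(f"length mismatch: {labels.shape} vs {scores.shape}")
    if labels.size == 0:
        raise ValueError("empty input")
    return labels, scores


def confusion_from_scores(labels, scores, threshold: float = 0.5) -> ConfusionCounts:
    """Confusion counts with call = (score >= threshold)."""
    labels, scores = _check_pair(labels, scores)
    calls = scores >= threshold
    pos = labels == 1
    return ConfusionCounts(
        TP=int(np.sum(calls & pos)),
        TN=int(np.sum(~calls & ~pos)),
        FP=int(np.sum(calls & ~pos)),
        FN=int(np.sum(~calls & pos)),
    )


def _safe_div(num: float, den: float) -> float:
    return num / den if den != 0 else 0.0


def scalar_metrics(c: ConfusionCounts) -> dict[str, float]:
    """ACC, Pre, Rec, F1 and MCC from confusion counts (0 on zero denominators)."""
    if c.total == 0:
        raise ValueError("no scored samples")
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    acc = _safe_div(tp + tn, tp + tn + fp + fn)
    pre = _safe_div(tp, tp + fp)
    rec = _safe_div(tp, tp + fn)
    f1 = _safe_div(2 * pre * rec, pre + rec)
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den)
    return {"ACC": acc, "Pre": pre, "Rec": rec, "F1": f1, "MCC": mcc}


def auroc(labels, scores) -> float:
    """Area under the ROC curve by the rank formulation (ties count half)."""
    labels, scores = _check_pair(labels, scores)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present for AUROC")
    ranks = rankdata(scores)  # average ranks handle ties
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def auprc(labels, scores) -> float:
    """Area under the precision-recall curve as average precision.

    Scores are swept from high to low over distinct thresholds; the AP sum
    uses the precision at each threshold weighted by the recall increment.
    """
    labels, scores = _check_pair(labels, scores)
    n_pos = int(np.sum(labels == 1))
    if n_pos == 0 or n_pos == labels.size:
        raise ValueError("both classes must be present for AUPRC")
    order = np.argsort(-scores, kind="stable")
    y = (labels[order] == 1).astype(float)
    s = scores[order]
    tp = np.cumsum(y)
    pred_pos = np.arange(1, len(y) + 1)
    # keep only the last index of each tied-score block
    block_end = np.r_[s[1:] != s[:-1], True]
    tp_b = tp[block_end]
    pp_b = pred_pos[block_end]
    precision = tp_b / pp_b
    recall = tp_b / n_pos
    d_recall = np.diff(np.r_[0.0, recall])
    return float(np.sum(precision * d_recall))


def per_class_accuracy(labels, calls) -> dict[str, float]:
    """Recall of each class: acc_pos = TP/(TP+FN), acc_neg = TN/(TN+FP)."""
    labels = np.asarray(labels)
    calls = np.asarray(calls)
    if labels.shape != calls.shape:
        raise ValueError("length mismatch")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    acc_pos = float(np.sum((labels == 1) & (calls == 1)) / n_pos)
    acc_neg = float(np.sum((labels == 0) & (calls == 0)) / n_neg)
    return {"acc_pos": acc_pos, "acc_neg": acc_neg}
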