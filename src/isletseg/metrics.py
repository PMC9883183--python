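"""Pixel-level evaluation metrics and the per-pixel certainty analysis.

Sensitivity SE = TP/(TP+FN), positive predictive value PPV = TP/(TP+FP),
IOU = |A∩B|/|A∪B|, F-score = 2·SE·PPV/(SE+PPV), and the area under the
precision–recall curve (AUPR) over all probability thresholds with
step-wise (rectangular) interpolation.  The certainty of pixel i is its
islet probability divided by the maximum islet probability in the same
image.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.metrics import precision_recall_curve

__all__ = ["ConfusionCounts", "MetricReport", "confusion_counts",
           "sensitivity", "ppv", "iou", "fscore", "aupr",
           "certainty_map", "evaluate_masks", "evaluate_probabilities"]


@dataclass
class ConfusionCounts:
    TP: int
    FP: int
    FN: int
    TN: int

    @property
    def total(self) -> int:
        return self.TP + self.FP + self.FN + self.TN


@dataclass
class MetricReport:
    SE: float
    PPV: float
    IOU: float
    F_score: float
    AUPR: float = float("nan")

    def to_dict(self) -> dict:
        return {"SE": self.SE, "PPV": self.PPV, "IOU": self.IOU,
                "F_score": self.F_score, "AUPR": self.AUPR}


def _check_binary_pair(pred, truth):
    pred = np.asarray(pred)
    truth = np.asarray(truth)
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    return pred.astype(bool), truth.astype(bool)


def confusion_counts(pred, truth) -> ConfusionCounts:
    """Exact pixel tallies of a predicted vs. reference binary mask."""
    pred, truth = _check_binary_pair(pred, truth)
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    tn = int(np.sum(~pred & ~truth))
    return ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn)


def sensitivity(c: ConfusionCounts, empty_truth_value: float = 1.0) -> float:
    """SE = TP/(TP+FN).  With no true positives to find, a prediction
    that is also empty scores ``empty_truth_value`` (default 1), any
    positive prediction scores 0."""
    if c.TP + c.FN == 0:
        return empty_truth_value if c.FP == 0 else 0.0
    return c.TP / (c.TP + c.FN)


def ppv(c: ConfusionCounts, empty_pred_value: float = 1.0) -> float:
    """PPV = TP/(TP+FP); an empty prediction against empty truth scores
    ``empty_pred_value``, against non-empty truth scores 0."""
    if c.TP + c.FP == 0:
        return empty_pred_value if c.FN == 0 else 0.0
    return c.TP / (c.TP + c.FP)


def iou(pred, truth) -> float:
    """Intersection over union of the two foreground pixel sets."""
    pred, truth = _check_binary_pair(pred, truth)
    union = np.sum(pred | truth)
    if union == 0:
        return 1.0  # both empty: perfect agreement
    return float(np.sum(pred & truth) / union)


def fscore(se: float, ppv_value: float) -> float:
    """F = 2·SE·PPV/(SE+PPV); 0 when both are 0."""
    if se + ppv_value == 0:
        return 0.0
    return 2.0 * se * ppv_value / (se + ppv_value)


def aupr(probs, truth) -> float:
    """Area under the precision–recall curve over all thresholds.

    Step-wise interpolation: sums precision·Δrecall across operating
    points, which avoids the optimistic linear interpolation in PR
    space.  Requires at least one positive reference pixel.
    """
    probs = np.asarray(probs, dtype=float).ravel()
    truth = np.asarray(truth).ravel().astype(bool)
    if probs.shape != truth.shape:
        raise ValueError("probability map and mask shapes differ")
    if not truth.any():
        raise ValueError("AUPR is undefined without positive reference pixels")
    precision, recall, _ = precision_recall_curve(truth.astype(int), probs)
    # curve is returned from high recall to low; integrate step-wise
    return float(-np.sum(np.diff(recall) * precision[:-1]))


def certainty_map(probs, islet_ref) -> np.ndarray:
    """Per-pixel certainty: p_i over the maximum probability among the
    reference islet pixels, clipped to [0, 1].

    ``islet_ref`` is normally the predicted islet mask; a ground-truth
    mask may be passed instead when available.
    """
    probs = np.asarray(probs, dtype=float)
    ref = np.asarray(islet_ref).astype(bool)
    if probs.shape != ref.shape:
        raise ValueError("probability map and reference mask shapes differ")
    if not ref.any():
        raise ValueError("certainty is undefined for an empty islet reference")
    denom = probs[ref].max()
    if denom == 0:
        raise ValueError("all reference probabilities are zero")
    return np.clip(probs / denom, 0.0, 1.0)


def evaluate_masks(pred, truth) -> MetricReport:
    """SE/PPV/IOU/F for one predicted mask against its reference."""
    c = confusion_counts(pred, truth)
    se = sensitivity(c)
    pv = ppv(c)
    return MetricReport(SE=se, PPV=pv, IOU=iou(pred, truth),
                        F_score=fscore(se, pv))


def evaluate_probabilities(probs, truth, threshold: float = 0.5) -> MetricReport:
    """Full report: threshold the probabilities for SE/PPV/IOU/F, and
    compute AUPR on the raw probabilities."""
    pred = np.asarray(probs) >= threshold
    report = evaluate_masks(pred, truth)
    report.AUPR = aupr(probs, truth)
    return report
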