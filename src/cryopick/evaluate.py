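"""Detection- and pixel-level scoring of picks against ground truth.

Detection-level: picks are matched one-to-one to ground-truth particles by
greedy nearest-center assignment within a tolerance (by default each truth
particle's own radius), giving TP/FP/FN counts, from which percentage
metrics are derived. The operational formulas are the ones consistent with
a TN-free detection setting:

    recall            = 100 * TP / (TP + FN)
    precision         = 100 * TP / (TP + FP)
    accuracy          = 100 * TP / (TP + FN + FP)
    misclassification = 100 * FN / (TP + FN)
    dice              = 100 * 2TP / (2TP + FP + FN)
    f1                = harmonic mean of recall and precision

When averaging over images, every metric is the arithmetic mean of the
per-image values except F1, which is the harmonic mean of the *averaged*
recall and precision. Pixel-level scoring compares binary masks directly.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple, Union

import numpy as np

from cryopick.errors import InvalidInputError
from cryopick.picks import ParticleCandidate, PickSet


@dataclass(frozen=True)
class GroundTruthParticle:
    """A manually labelled (or simulated) particle."""

    center: Tuple[float, float]  # (row, col)
    radius_or_halfside: float
    shape: str  # "circle" | "square"


@dataclass(frozen=True)
class ConfusionCounts:
    """Detection tallies; ``total_truth`` equals TP + FN."""

    TP: int
    FP: int
    FN: int
    TN: Optional[int] = None

    def __post_init__(self) -> None:
        if min(self.TP, self.FP, self.FN) < 0:
            raise InvalidInputError("counts must be non-negative")
        if self.TN is not None and self.TN < 0:
            raise InvalidInputError("counts must be non-negative")

    @property
    def total_truth(self) -> int:
        return self.TP + self.FN


@dataclass(frozen=True)
class DetectionReport:
    """Percentage metrics in [0, 100]; NaN marks an undefined metric."""

    recall: float
    precision: float
    f1: float
    accuracy: float
    misclassification: float
    dice: float

    def as_dict(self) -> dict:
        return {
            "recall": self.recall,
            "precision": self.precision,
            "f1": self.f1,
            "accuracy": self.accuracy,
            "misclassification": self.misclassification,
            "dice": self.dice,
        }


def match_detections(picks: Union[PickSet, Sequence[ParticleCandidate]],
                     truth: Sequence[GroundTruthParticle],
                     tol: Union[float, str] = "radius") -> ConfusionCounts:
    """Greedy one-to-one matching of picks to ground truth.

    Candidate pairs with matching shape and center distance within the
    tolerance are accepted in ascending-distance order, each pick and truth
    used at most once. ``tol`` is a pixel distance, or ``"radius"`` to use
    each truth particle's own radius (half-side for squares).
    """
    pick_list = list(picks)
    if isinstance(tol, str) and tol != "radius":
        raise InvalidInputError(f"unknown tolerance {tol!r}")
    if not isinstance(tol, str) and tol <= 0:
        raise InvalidInputError("tol must be positive")
    pairs = []
    for i, p in enumerate(pick_list):
        for j, t in enumerate(truth):
            if p.shape != t.shape:
                continue
            dist = math.hypot(p.center[0] - t.center[0],
                              p.center[1] - t.center[1])
            limit = t.radius_or_halfside if tol == "radius" else float(tol)
            if dist <= limit:
                pairs.append((dist, i, j))
    pairs.sort()
    used_picks: set = set()
    used_truth: set = set()
    tp = 0
    for _dist, i, j in pairs:
        if i in used_picks or j in used_truth:
            continue
        used_picks.add(i)
        used_truth.add(j)
        tp += 1
    return ConfusionCounts(TP=tp, FP=len(pick_list) - tp,
                           FN=len(truth) - tp)


def _ratio(num: float, den: float) -> float:
    return 100.0 * num / den if den > 0 else float("nan")


def detection_metrics(counts: ConfusionCounts) -> DetectionReport:
    """Percentage metrics from confusion counts.

    A metric whose denominator is zero is reported as NaN (undefined), not
    as 0 — except recall, which is 0 when there are truths but no TP.
    """
    tp, fp, fn = counts.TP, counts.FP, counts.FN
    recall = _ratio(tp, tp + fn)
    precision = _ratio(tp, tp + fp)
    if math.isnan(recall) or math.isnan(precision) or recall + precision == 0:
        f1 = float("nan") if (math.isnan(recall) or math.isnan(precision)) else 0.0
    else:
        f1 = 2.0 * recall * precision / (recall + precision)
    return DetectionReport(
        recall=recall,
        precision=precision,
        f1=f1,
        accuracy=_ratio(tp, tp + fn + fp),
        misclassification=_ratio(fn, tp + fn),
        dice=_ratio(2 * tp, 2 * tp + fp + fn),
    )


def aggregate_reports(reports: Sequence[DetectionReport]) -> DetectionReport:
    """Average per-image reports.

    Arithmetic mean per metric, except F1, which is recomputed as the
    harmonic mean of the averaged recall and averaged precision (this is the
    aggregation that makes the averaged metrics mutually consistent).
    """
    if not reports:
        raise InvalidInputError("need at least one report")
    mean = lambda vals: float(np.mean(vals))
    recall = mean([r.recall for r in reports])
    precision = mean([r.precision for r in reports])
    if recall + precision > 0:
        f1 = 2.0 * recall * precision / (recall + precision)
    else:
        f1 = float("nan")
    return DetectionReport(
        recall=recall,
        precision=precision,
        f1=f1,
        accuracy=mean([r.accuracy for r in reports]),
        misclassification=mean([r.misclassification for r in reports]),
        dice=mean([r.dice for r in reports]),
    )


def pixel_metrics(mask: np.ndarray, truth_mask: np.ndarray,
                  literal: bool = False) -> dict:
    """Pixel-level overlap metrics between a mask and its ground truth.

    Returns accuracy, dice and misclassification percentages. With
    ``literal=True`` the alternative historical forms
    ``accuracy = TP/(TP+TN)`` and ``misclassification = (FP+TN)/total`` are
    reported instead (pixel-level only; kept for comparability, not
    recommended).
    """
    mask = np.asarray(mask, dtype=bool)
    truth_mask = np.asarray(truth_mask, dtype=bool)
    if mask.shape != truth_mask.shape:
        raise InvalidInputError(
            f"shape mismatch: {mask.shape} vs {truth_mask.shape}")
    tp = int(np.sum(mask & truth_mask))
    tn = int(np.sum(~mask & ~truth_mask))
    fp = int(np.sum(mask & ~truth_mask))
    fn = int(np.sum(~mask & truth_mask))
    total = mask.size
    dice = _ratio(2 * tp, 2 * tp + fp + fn) if (tp + fp + fn) else 100.0
    if literal:
        accuracy = _ratio(tp, tp + tn)
        misclassification = _ratio(fp + tn, total)
    else:
        accuracy = _ratio(tp + tn, total)
        misclassification = 100.0 - accuracy
    return {
        "accuracy": accuracy,
        "dice": dice,
        "misclassification": misclassification,
        "counts": ConfusionCounts(TP=tp, FP=fp, FN=fn, TN=tn),
    }


def score_picks(picks: Union[PickSet, Sequence[ParticleCandidate]],
                truth: Sequence[GroundTruthParticle],
                tol: Union[float, str] = "radius") -> DetectionReport:
    """Convenience: match then compute metrics in one call."""
    return detection_metrics(match_detections(picks, truth, tol))
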