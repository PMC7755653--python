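"""ROC construction and probability-threshold selection against PI-RADS.

Thresholds on the model's continuous tumor-probability score are chosen to
reproduce the radiologist's working points: the patient-level ROC is built
from observed scores, the radiologist's (sensitivity, specificity) at the
PI-RADS >= 3 and >= 4 cutoffs on the same examinations serves as the
reference, and the candidate threshold minimizing Euclidean distance to each
reference point is selected (ties broken toward the smaller threshold, i.e.
higher sensitivity).  Three kinds of threshold sets exist: *fixed* (computed
once from the most recent window of the prior cohort), *dynamic*
(prospectively readjusted on a sliding window), and *limit* (hindsight, from
the full current cohort).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .cohort import ExamRecord
from .errors import DegenerateInputError
from .fusion import GroundTruth, binarize, pirads_patient_category

__all__ = [
    "WorkingPoint",
    "ThresholdSet",
    "RocCurve",
    "roc_points",
    "match_threshold",
    "pirads_reference_points",
    "compute_thresholds",
]


@dataclass(frozen=True)
class WorkingPoint:
    """A (sensitivity, specificity) pair, optionally tied to a threshold."""

    sensitivity: float
    specificity: float
    threshold: float | None = None

    def __post_init__(self):
        if not (0.0 <= self.sensitivity <= 1.0 and 0.0 <= self.specificity <= 1.0):
            raise ValueError("sensitivity and specificity must lie in [0, 1]")


@dataclass(frozen=True)
class ThresholdSet:
    """The pair of probability thresholds emulating PI-RADS >= 3 / >= 4."""

    t3: float
    t4: float
    kind: str  # "fixed" | "dynamic" | "limit"

    def __post_init__(self):
        if self.kind not in ("fixed", "dynamic", "limit"):
            raise ValueError(f"unknown threshold kind {self.kind!r}")
        if self.t3 > self.t4:
            warnings.warn(
                f"t3 ({self.t3:.4f}) exceeds t4 ({self.t4:.4f}); the >=3-emulating "
                "threshold is usually the more sensitive one",
                stacklevel=2,
            )


@dataclass
class RocCurve:
    """Operating points at every candidate threshold, ascending in threshold."""

    thresholds: np.ndarray
    sensitivity: np.ndarray
    specificity: np.ndarray

    def __post_init__(self):
        self.thresholds = np.asarray(self.thresholds, dtype=float)
        self.sensitivity = np.asarray(self.sensitivity, dtype=float)
        self.specificity = np.asarray(self.specificity, dtype=float)
        if not (np.diff(self.thresholds) > 0).all():
            raise ValueError("thresholds must be strictly increasing")
        if (np.diff(self.sensitivity) > 1e-12).any():
            raise ValueError("sensitivity must be non-increasing along thresholds")
        if (np.diff(self.specificity) < -1e-12).any():
            raise ValueError("specificity must be non-decreasing along thresholds")

    def __len__(self) -> int:
        return len(self.thresholds)

    def point(self, i: int) -> WorkingPoint:
        return WorkingPoint(
            sensitivity=float(self.sensitivity[i]),
            specificity=float(self.specificity[i]),
            threshold=float(self.thresholds[i]),
        )

    def auc(self) -> float:
        """Trapezoidal area under the (FPR, TPR) curve."""
        fpr = 1.0 - self.specificity
        order = np.argsort(fpr)
        return float(np.trapezoid(self.sensitivity[order], fpr[order]))


def roc_points(scores: Sequence[float], labels: Sequence[bool]) -> RocCurve:
    """ROC over the candidate thresholds: every unique observed score plus a
    sentinel above the maximum (the all-negative classifier).  Binarization is
    inclusive >=."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    if scores.shape != labels.shape or scores.ndim != 1:
        raise ValueError("scores and labels must be equal-length 1-D sequences")
    n_pos = int(labels.sum())
    n_neg = int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("ROC requires at least one positive and one negative label")
    thresholds = np.unique(scores)
    thresholds = np.append(thresholds, thresholds[-1] + 1.0)  # sentinel: nothing called positive
    pos_sorted = np.sort(scores[labels])
    neg_sorted = np.sort(scores[~labels])
    tp = n_pos - np.searchsorted(pos_sorted, thresholds, side="left")
    tn = np.searchsorted(neg_sorted, thresholds, side="left")
    return RocCurve(thresholds=thresholds, sensitivity=tp / n_pos, specificity=tn / n_neg)


def match_threshold(roc: RocCurve, target: WorkingPoint) -> float:
    """The candidate threshold whose working point is Euclidean-closest to the
    target; on ties the smaller threshold (higher sensitivity) wins."""
    d2 = (roc.sensitivity - target.sensitivity) ** 2 + (roc.specificity - target.specificity) ** 2
    return float(roc.thresholds[int(np.argmin(d2))])  # argmin: first (= smallest threshold)


def pirads_reference_points(
    exams: Sequence[ExamRecord], truths: Sequence[GroundTruth]
) -> dict[int, WorkingPoint]:
    """Radiologist (sens, spec) at the PI-RADS >= 3 and >= 4 cutoffs."""
    cats = np.array([pirads_patient_category(e) for e in exams])
    disease = np.array([t.patient_spc for t in truths], dtype=bool)
    n_pos = int(disease.sum())
    n_neg = int((~disease).sum())
    if n_pos == 0 or n_neg == 0:
        raise DegenerateInputError("reference requires both diseased and non-diseased patients")
    points = {}
    for cutoff in (3, 4):
        calls = np.array([binarize(c, cutoff) for c in cats])
        points[cutoff] = WorkingPoint(
            sensitivity=float((calls & disease).sum() / n_pos),
            specificity=float((~calls & ~disease).sum() / n_neg),
        )
    return points


def compute_thresholds(
    exams: Sequence[ExamRecord],
    truths: Sequence[GroundTruth],
    kind: str = "fixed",
    reference: dict[int, WorkingPoint] | None = None,
) -> ThresholdSet:
    """Calibrate t3/t4 on a window of examinations.

    The patient-level ROC is built from the exams' model scores against the
    fused ground truth; the reference working points default to the PI-RADS
    >= 3 / >= 4 performance computed on the same window.
    """
    exams = list(exams)
    truths = list(truths)
    if len(exams) != len(truths):
        raise ValueError("exams and truths must align")
    scores = [e.unet_patient_score for e in exams]
    labels = [t.patient_spc for t in truths]
    roc = roc_points(scores, labels)
    if reference is None:
        reference = pirads_reference_points(exams, truths)
    return ThresholdSet(
        t3=match_threshold(roc, reference[3]),
        t4=match_threshold(roc, reference[4]),
        kind=kind,
    )
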