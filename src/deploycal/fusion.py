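"""Fusion of targeted and systematic biopsy histopathology into ground truth.

Clinically significant prostate cancer (sPC) is ISUP grade group >= 2.  The
combined reference uses all available histology: a lesion is sPC-positive if
any of its targeted cores is significant; a sextant is positive if any
systematic core located in it is significant OR a significant targeted core's
lesion overlaps it ("maximum evidence" rule); the patient is positive if any
core is significant.  This captures sPC found outside radiologist lesions by
the systematic saturation cores.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .cohort import SEXTANTS, ExamRecord
from .errors import DomainError

__all__ = [
    "GroundTruth",
    "is_significant",
    "fuse",
    "pirads_patient_category",
    "pirads_sextant_category",
    "binarize",
]


@dataclass
class GroundTruth:
    """sPC labels at patient, sextant, and lesion level for one examination."""

    patient_spc: bool
    sextant_spc: dict[str, bool] = field(default_factory=dict)
    lesion_spc: dict[str, bool] = field(default_factory=dict)


def is_significant(isup: int) -> bool:
    """True iff the ISUP grade group (0 = benign) denotes sPC (>= 2)."""
    if not 0 <= isup <= 5:
        raise DomainError(f"ISUP grade group {isup} outside 0-5")
    return isup >= 2


def fuse(exam: ExamRecord) -> GroundTruth:
    """Fuse the exam's targeted and systematic cores into a GroundTruth."""
    lesion_spc = {lesion.lesion_id: False for lesion in exam.lesions}
    sextant_spc = {s: False for s in SEXTANTS}
    lesion_sextants = {lesion.lesion_id: lesion.sextants_overlapped for lesion in exam.lesions}
    for core in exam.cores:
        if not is_significant(core.isup_grade_group):
            continue
        if core.origin == "systematic":
            sextant_spc[core.sextant] = True
        else:
            lesion_spc[core.lesion_id] = True
            for s in lesion_sextants[core.lesion_id]:
                sextant_spc[s] = True
    patient_spc = any(sextant_spc.values()) or any(lesion_spc.values())
    return GroundTruth(patient_spc=patient_spc, sextant_spc=sextant_spc, lesion_spc=lesion_spc)


def pirads_patient_category(exam: ExamRecord) -> int:
    """The index (maximum) lesion PI-RADS category; 1 when no lesion was seen."""
    if not exam.lesions:
        return 1
    return max(lesion.pirads for lesion in exam.lesions)


def pirads_sextant_category(exam: ExamRecord) -> dict[str, int]:
    """Per-sextant PI-RADS: the maximum category of lesions overlapping it."""
    cats = {s: 1 for s in SEXTANTS}
    for lesion in exam.lesions:
        for s in lesion.sextants_overlapped:
            cats[s] = max(cats[s], lesion.pirads)
    return cats


def binarize(value, cutoff) -> bool:
    """Inclusive->= binarization used for both PI-RADS categories and scores."""
    return bool(value >= cutoff)
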