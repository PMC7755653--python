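import numpy as np
import pytest

from deploycal.cohort import SEXTANTS, Cohort, CoreResult, ExamRecord, LesionRecord
from deploycal.synthetic import default_paper_config, generate_cohort


def make_exam(
    patient_id="P0",
    time_index=0,
    pirads_lesions=(),
    cores=(),
    patient_score=0.5,
    sextant_scores=None,
    **kwargs,
):
    """Minimal valid examination for unit tests.

    ``pirads_lesions``: sequence of (pirads, sextants) pairs; lesion ids are
    ``{patient_id}-L{j}``.  ``cores``: sequence of (origin, sextant, isup,
    lesion_index-or-None).
    """
    lesions = [
        LesionRecord(
            lesion_id=f"{patient_id}-L{j}",
            patient_id=patient_id,
            pirads=pirads,
            zone="PZ",
            sextants_overlapped=tuple(sextants),
        )
        for j, (pirads, sextants) in enumerate(pirads_lesions)
    ]
    core_records = [
        CoreResult(
            core_id=f"{patient_id}-C{k}",
            patient_id=patient_id,
            origin=origin,
            sextant=sextant,
            isup_grade_group=isup,
            lesion_id=f"{patient_id}-L{lesion_idx}" if lesion_idx is not None else None,
        )
        for k, (origin, sextant, isup, lesion_idx) in enumerate(cores)
    ]
    return ExamRecord(
        patient_id=patient_id,
        time_index=time_index,
        referral="biopsy_naive",
        psa=6.0,
        unet_patient_score=patient_score,
        unet_sextant_scores=sextant_scores or {s: 0.1 for s in SEXTANTS},
        lesions=lesions,
        cores=core_records,
        **kwargs,
    )


@pytest.fixture
def two_patient_cohort():
    exam_a = make_exam(
        "A", 0,
        pirads_lesions=[(4, ("LB", "LM"))],
        cores=[("targeted", "LB", 3, 0), ("systematic", "RB", 0, None)],
        patient_score=0.72,
    )
    exam_b = make_exam("B", 1, patient_score=0.08)
    return Cohort([exam_a, exam_b])


@pytest.fixture(scope="session")
def synthetic_cohort_300():
    """One fixed-seed synthetic cohort reused by calibration-level tests."""
    cfg = default_paper_config(n_patients=300, seed=42)
    return generate_cohort(cfg)


def truths_of(cohort, bundle):
    return [bundle[e.patient_id] for e in cohort]
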