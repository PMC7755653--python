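"""Conjunction ("virtual second reader") analysis at patient/sextant/lesion level.

A unit is conjunction-positive only when both the radiologist (PI-RADS >= 3 or
>= 4) and the model (score >= threshold) call it positive.  For each level and
pairing the paired 2x2x2 table is built, PPV/NPV are reported with their
counts, and the conjunction is compared against the radiologist rule alone
with the paired relative-predictive-value test; p-values are Holm-adjusted
within each level.  Lesion-level analysis is conditioned on the clinically
identified lesions, so there is no model-alone lesion rule.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cohort import SEXTANTS, Cohort, ExamRecord
from .dxstats import (
    PairedTable,
    holm,
    metrics_from_counts,
    relative_pv_test,
)
from .errors import AlignmentError, DegenerateInputError, MissingDataError
from .fusion import GroundTruth, pirads_sextant_category

__all__ = [
    "DetectionVector",
    "conjunction",
    "lesion_detection",
    "patient_detection",
    "sextant_detection",
    "cooccurrence_report",
]


@dataclass
class DetectionVector:
    """Boolean calls and disease labels over a fixed set of units."""

    ids: tuple
    calls: np.ndarray
    disease: np.ndarray

    def __post_init__(self):
        self.calls = np.asarray(self.calls, dtype=bool)
        self.disease = np.asarray(self.disease, dtype=bool)
        if not (len(self.ids) == len(self.calls) == len(self.disease)):
            raise AlignmentError("ids, calls, and disease labels must have equal length")

    def __len__(self) -> int:
        return len(self.ids)


def conjunction(a: DetectionVector, b: DetectionVector) -> DetectionVector:
    """Elementwise AND of two detection vectors over the same units."""
    if a.ids != b.ids:
        raise AlignmentError("detection vectors describe different units")
    if not np.array_equal(a.disease, b.disease):
        raise AlignmentError("detection vectors carry conflicting disease labels")
    return DetectionVector(ids=a.ids, calls=a.calls & b.calls, disease=a.disease)


def lesion_detection(exam: ExamRecord, threshold: float) -> dict[str, bool]:
    """Model call per clinical lesion: lesion score >= threshold, the score
    defaulting to the map maximum inside the union of the lesion's VOIs."""
    calls = {}
    for lesion in exam.lesions:
        score = lesion.unet_lesion_score
        if score is None:
            if exam.prob_map is None or (lesion.t2w_voi is None and lesion.dwi_voi is None):
                raise MissingDataError(
                    f"lesion {lesion.lesion_id!r} has neither a score nor a map with a VOI"
                )
            if lesion.t2w_voi is not None and lesion.dwi_voi is not None:
                voi = lesion.t2w_voi.union(lesion.dwi_voi)
            else:
                voi = lesion.t2w_voi if lesion.t2w_voi is not None else lesion.dwi_voi
            score = exam.prob_map.max_inside(voi)
        calls[lesion.lesion_id] = bool(score >= threshold)
    return calls


def _truth_list(cohort: Cohort, truths) -> list[GroundTruth]:
    if hasattr(truths, "truths"):
        return [truths[e.patient_id] for e in cohort]
    return list(truths)


def patient_detection(cohort: Cohort, truths, rule: str, cutoff: float) -> DetectionVector:
    """Patient-level detection under a PI-RADS cutoff or model threshold."""
    truths = _truth_list(cohort, truths)
    ids = tuple(e.patient_id for e in cohort)
    disease = np.array([t.patient_spc for t in truths])
    if rule == "pirads":
        from .fusion import pirads_patient_category

        calls = np.array([pirads_patient_category(e) >= cutoff for e in cohort])
    elif rule == "unet":
        calls = np.array([e.unet_patient_score >= cutoff for e in cohort])
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return DetectionVector(ids, calls, disease)


def sextant_detection(cohort: Cohort, truths, rule: str, cutoff) -> DetectionVector:
    """Sextant-level detection; ``cutoff`` may be a scalar or per-exam array."""
    truths = _truth_list(cohort, truths)
    ids = tuple((e.patient_id, s) for e in cohort for s in SEXTANTS)
    disease = np.array([t.sextant_spc[s] for t in truths for s in SEXTANTS])
    cut = np.asarray(cutoff, dtype=float)
    cut = np.repeat(cut, len(SEXTANTS)) if cut.ndim else cut
    if rule == "pirads":
        cats = np.array([pirads_sextant_category(e)[s] for e in cohort for s in SEXTANTS])
        calls = cats >= cut
    elif rule == "unet":
        scores = np.array([e.unet_sextant_scores[s] for e in cohort for s in SEXTANTS])
        calls = scores >= cut
    else:
        raise ValueError(f"unknown rule {rule!r}")
    return DetectionVector(ids, calls, disease)


def lesion_detection_vector(cohort: Cohort, truths, rule: str, cutoff) -> DetectionVector:
    truths = _truth_list(cohort, truths)
    ids, calls, disease = [], [], []
    cut = np.asarray(cutoff, dtype=float)
    for i, (exam, truth) in enumerate(zip(cohort, truths)):
        thr = float(cut[i]) if cut.ndim else float(cut)
        model_calls = lesion_detection(exam, thr) if rule == "unet" else None
        for lesion in exam.lesions:
            ids.append((exam.patient_id, lesion.lesion_id))
            disease.append(truth.lesion_spc[lesion.lesion_id])
            if rule == "pirads":
                calls.append(lesion.pirads >= thr)
            else:
                calls.append(model_calls[lesion.lesion_id])
    return DetectionVector(tuple(ids), np.array(calls, dtype=bool), np.array(disease, dtype=bool))


def _pv_row(vec: DetectionVector) -> dict:
    from .dxstats import ConfusionCounts

    m = metrics_from_counts(ConfusionCounts.from_calls(vec.calls, vec.disease))
    row = {}
    for name, metric in (("ppv", m.ppv), ("npv", m.npv)):
        row[f"{name}_pct"] = metric.pct if metric else None
        row[f"{name}_num"] = metric.numerator if metric else 0
        row[f"{name}_den"] = metric.denominator if metric else 0
    return row


def cooccurrence_report(
    cohort: Cohort,
    truths,
    model_thresholds: Mapping[str, float],
    pirads_cutoffs: Sequence[int] = (3, 4),
) -> pd.DataFrame:
    """Per-level PPV/NPV of each rule and each conjunction, with raw and
    Holm-adjusted relative-predictive-value p-values (conjunction vs the
    radiologist rule alone).  Degenerate comparisons yield None markers."""
    rows = []
    for level in ("patient", "sextant", "lesion"):
        if level == "patient":
            build = lambda rule, cut: patient_detection(cohort, truths, rule, cut)
        elif level == "sextant":
            build = lambda rule, cut: sextant_detection(cohort, truths, rule, cut)
        else:
            build = lambda rule, cut: lesion_detection_vector(cohort, truths, rule, cut)

        pirads_vecs = {c: build("pirads", c) for c in pirads_cutoffs}
        model_vecs = {name: build("unet", thr) for name, thr in model_thresholds.items()}

        level_rows = []
        for c in pirads_cutoffs:
            level_rows.append({"level": level, "rule": f"pirads>={c}", **_pv_row(pirads_vecs[c])})
        if level != "lesion":  # model-alone rules are defined on complete units only
            for name, vec in model_vecs.items():
                level_rows.append({"level": level, "rule": f"unet>={name}", **_pv_row(vec)})
        tests = []
        for name, vec in model_vecs.items():
            for c in pirads_cutoffs:
                conj = conjunction(vec, pirads_vecs[c])
                row = {
                    "level": level,
                    "rule": f"unet>={name} & pirads>={c}",
                    "baseline": f"pirads>={c}",
                    **_pv_row(conj),
                }
                try:
                    table = PairedTable.from_vectors(conj.calls, pirads_vecs[c].calls, conj.disease)
                    res = relative_pv_test(table)
                    row.update(
                        {
                            "rppv": res.rppv,
                            "p_ppv_raw": res.p_ppv,
                            "rnpv": res.rnpv,
                            "p_npv_raw": res.p_npv,
                        }
                    )
                    tests.append(row)
                except DegenerateInputError as exc:
                    row.update({"rppv": None, "p_ppv_raw": None, "rnpv": None, "p_npv_raw": None})
                    row["note"] = str(exc)
                level_rows.append(row)
        raw = [r["p_ppv_raw"] for r in tests] + [r["p_npv_raw"] for r in tests]
        if raw:
            adj = holm(raw)
            for i, r in enumerate(tests):
                r["p_ppv_holm"] = float(adj[i])
                r["p_npv_holm"] = float(adj[len(tests) + i])
        rows.extend(level_rows)
    return pd.DataFrame(rows)
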