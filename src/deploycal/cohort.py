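"""Core data model for examinations, lesions, biopsy cores, and model scores.

One examination = one patient visit carrying the radiologist's PI-RADS lesions,
the biopsy cores (targeted at lesions and systematic per sextant), and the
classifier's continuous tumor-probability scores at patient, sextant, and
lesion level, optionally backed by a full 3-D probability map.

Cohorts round-trip through three CSV tables (patients / lesions / cores) with
optional NIfTI sidecars for voxel data.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import ReferentialError, SchemaError
from .segmentation import VoxelMask, VoxelProbabilityMap

__all__ = [
    "SEXTANTS",
    "REFERRALS",
    "CoreResult",
    "LesionRecord",
    "ExamRecord",
    "Cohort",
    "ValidationReport",
    "load_cohort",
    "write_cohort",
    "validate_cohort",
]

#: The six biopsy sextants, {left, right} x {base, mid, apex}, as 2-letter codes.
SEXTANTS: tuple[str, ...] = ("LB", "LM", "LA", "RB", "RM", "RA")

REFERRALS: tuple[str, ...] = ("biopsy_naive", "previously_biopsied", "active_surveillance")


@dataclass
class CoreResult:
    """A single biopsy core with its ISUP grade group (0 = benign)."""

    core_id: str
    patient_id: str
    origin: str  # "targeted" | "systematic"
    sextant: str
    isup_grade_group: int
    lesion_id: str | None = None  # required for targeted cores


@dataclass
class LesionRecord:
    """One radiologist-identified MRI lesion."""

    lesion_id: str
    patient_id: str
    pirads: int
    zone: str  # "PZ" | "TZ"
    sextants_overlapped: tuple[str, ...]
    t2w_voi: VoxelMask | None = None
    dwi_voi: VoxelMask | None = None
    unet_lesion_score: float | None = None


@dataclass
class ExamRecord:
    """One patient examination with lesions, cores, and model scores."""

    patient_id: str
    time_index: int
    referral: str
    unet_patient_score: float
    unet_sextant_scores: dict[str, float]
    psa: float | None = None
    lesions: list[LesionRecord] = field(default_factory=list)
    cores: list[CoreResult] = field(default_factory=list)
    prob_map: VoxelProbabilityMap | None = None
    prostate_mask: VoxelMask | None = None


@dataclass
class Cohort:
    """Chronologically ordered examinations with unique patient ids."""

    exams: list[ExamRecord] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.exams)

    def __iter__(self):
        return iter(self.exams)

    def __getitem__(self, i):
        return self.exams[i]


@dataclass
class ValidationReport:
    """Invariant violations found in a cohort; empty iff the cohort is valid."""

    violations: list[str] = field(default_factory=list)

    def add(self, message: str) -> None:
        self.violations.append(message)

    @property
    def ok(self) -> bool:
        return not self.violations

    def __len__(self) -> int:
        return len(self.violations)


def validate_cohort(cohort: Cohort) -> ValidationReport:
    """Check every structural invariant; violations are data, not exceptions."""
    report = ValidationReport()
    seen_ids: set[str] = set()
    last_time = -math.inf
    for exam in cohort:
        pid = exam.patient_id
        if pid in seen_ids:
            report.add(f"duplicate patient_id {pid!r}")
        seen_ids.add(pid)
        if exam.time_index <= last_time:
            report.add(f"patient {pid!r}: time_index {exam.time_index} not strictly increasing")
        last_time = max(last_time, exam.time_index)
        if exam.time_index < 0:
            report.add(f"patient {pid!r}: negative time_index")
        if exam.referral not in REFERRALS:
            report.add(f"patient {pid!r}: unknown referral {exam.referral!r}")
        if exam.psa is not None and exam.psa < 0:
            report.add(f"patient {pid!r}: negative PSA")
        if not 0.0 <= exam.unet_patient_score <= 1.0:
            report.add(f"patient {pid!r}: patient score outside [0, 1]")
        if set(exam.unet_sextant_scores) != set(SEXTANTS):
            report.add(f"patient {pid!r}: sextant scores must cover exactly {SEXTANTS}")
        else:
            for s, v in exam.unet_sextant_scores.items():
                if not 0.0 <= v <= 1.0:
                    report.add(f"patient {pid!r}: sextant {s} score outside [0, 1]")
        lesion_ids = set()
        for lesion in exam.lesions:
            lid = lesion.lesion_id
            if lid in lesion_ids:
                report.add(f"lesion {lid!r}: duplicate lesion_id")
            lesion_ids.add(lid)
            if lesion.patient_id != pid:
                report.add(f"lesion {lid!r}: patient_id mismatch")
            if lesion.pirads not in (2, 3, 4, 5):
                report.add(f"lesion {lid!r}: pirads {lesion.pirads} outside 2-5")
            if lesion.zone not in ("PZ", "TZ"):
                report.add(f"lesion {lid!r}: unknown zone {lesion.zone!r}")
            if not lesion.sextants_overlapped:
                report.add(f"lesion {lid!r}: sextants_overlapped is empty")
            elif not set(lesion.sextants_overlapped) <= set(SEXTANTS):
                report.add(f"lesion {lid!r}: unknown sextant codes")
            if lesion.unet_lesion_score is not None and not 0.0 <= lesion.unet_lesion_score <= 1.0:
                report.add(f"lesion {lid!r}: lesion score outside [0, 1]")
        for core in exam.cores:
            cid = core.core_id
            if core.patient_id != pid:
                report.add(f"core {cid!r}: patient_id mismatch")
            if core.origin not in ("targeted", "systematic"):
                report.add(f"core {cid!r}: unknown origin {core.origin!r}")
            if core.origin == "targeted" and core.lesion_id not in lesion_ids:
                report.add(f"core {cid!r}: targeted core references absent lesion {core.lesion_id!r}")
            if core.sextant not in SEXTANTS:
                report.add(f"core {cid!r}: unknown sextant {core.sextant!r}")
            if not 0 <= core.isup_grade_group <= 5:
                report.add(f"core {cid!r}: isup_grade_group {core.isup_grade_group} outside 0-5")
        if exam.prob_map is not None:
            if exam.prostate_mask is not None:
                inside = exam.prob_map.max_inside(exam.prostate_mask)
            else:
                inside = float(exam.prob_map.data.max())
            if abs(inside - exam.unet_patient_score) > 1e-6:
                report.add(
                    f"patient {pid!r}: patient score {exam.unet_patient_score:.6f} != "
                    f"max map probability {inside:.6f}"
                )
    return report


# ---------------------------------------------------------------------------
# CSV / NIfTI round-trip
# ---------------------------------------------------------------------------

_PATIENT_COLS = (
    ["patient_id", "time_index", "referral", "psa", "unet_patient_score"]
    + [f"unet_sextant_{s}" for s in SEXTANTS]
    + ["prob_map", "prostate_mask"]
)
_LESION_COLS = [
    "lesion_id",
    "patient_id",
    "pirads",
    "zone",
    "sextants_overlapped",
    "unet_lesion_score",
    "t2w_voi",
    "dwi_voi",
]
_CORE_COLS = ["core_id", "patient_id", "origin", "lesion_id", "sextant", "isup_grade_group"]


def _require_columns(df: pd.DataFrame, required: list[str], table: str) -> None:
    for col in required:
        if col not in df.columns:
            raise SchemaError(f"{table} is missing required column {col!r}")


def _write_nifti(arr: np.ndarray, spacing, path: str) -> None:
    import nibabel as nib

    affine = np.diag(list(spacing) + [1.0])
    nib.save(nib.Nifti1Image(np.asarray(arr, dtype=np.float32), affine), path)


def _read_nifti(path: str) -> tuple[np.ndarray, tuple[float, float, float]]:
    import nibabel as nib

    img = nib.load(path)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.get_fdata()), spacing


def write_cohort(cohort: Cohort, path: str) -> None:
    """Write ``patients.csv``/``lesions.csv``/``cores.csv`` (+ NIfTI sidecars)
    such that :func:`load_cohort` inverts the write."""
    os.makedirs(path, exist_ok=True)
    patients, lesions, cores = [], [], []
    for exam in cohort:
        row = {
            "patient_id": exam.patient_id,
            "time_index": exam.time_index,
            "referral": exam.referral,
            "psa": exam.psa,
            "unet_patient_score": exam.unet_patient_score,
            "prob_map": None,
            "prostate_mask": None,
        }
        for s in SEXTANTS:
            row[f"unet_sextant_{s}"] = exam.unet_sextant_scores[s]
        if exam.prob_map is not None:
            rel = f"{exam.patient_id}_probmap.nii.gz"
            _write_nifti(exam.prob_map.data, exam.prob_map.spacing, os.path.join(path, rel))
            row["prob_map"] = rel
        if exam.prostate_mask is not None:
            rel = f"{exam.patient_id}_prostate.nii.gz"
            _write_nifti(exam.prostate_mask.data, exam.prostate_mask.spacing, os.path.join(path, rel))
            row["prostate_mask"] = rel
        patients.append(row)
        for lesion in exam.lesions:
            lrow = {
                "lesion_id": lesion.lesion_id,
                "patient_id": lesion.patient_id,
                "pirads": lesion.pirads,
                "zone": lesion.zone,
                "sextants_overlapped": "|".join(lesion.sextants_overlapped),
                "unet_lesion_score": lesion.unet_lesion_score,
                "t2w_voi": None,
                "dwi_voi": None,
            }
            for attr in ("t2w_voi", "dwi_voi"):
                mask = getattr(lesion, attr)
                if mask is not None:
                    rel = f"{lesion.lesion_id}_{attr}.nii.gz"
                    _write_nifti(mask.data, mask.spacing, os.path.join(path, rel))
                    lrow[attr] = rel
            lesions.append(lrow)
        for core in exam.cores:
            cores.append(
                {
                    "core_id": core.core_id,
                    "patient_id": core.patient_id,
                    "origin": core.origin,
                    "lesion_id": core.lesion_id,
                    "sextant": core.sextant,
                    "isup_grade_group": core.isup_grade_group,
                }
            )
    pd.DataFrame(patients, columns=_PATIENT_COLS).to_csv(os.path.join(path, "patients.csv"), index=False, float_format="%.17g")
    pd.DataFrame(lesions, columns=_LESION_COLS).to_csv(os.path.join(path, "lesions.csv"), index=False, float_format="%.17g")
    pd.DataFrame(cores, columns=_CORE_COLS).to_csv(os.path.join(path, "cores.csv"), index=False)


def _opt_float(value) -> float | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return float(value)


def _opt_str(value) -> str | None:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    return str(value)


def load_cohort(path: str) -> Cohort:
    """Load and validate a cohort written by :func:`write_cohort`."""
    pdf = pd.read_csv(os.path.join(path, "patients.csv"), float_precision="round_trip")
    ldf = pd.read_csv(os.path.join(path, "lesions.csv"), float_precision="round_trip")
    cdf = pd.read_csv(os.path.join(path, "cores.csv"))
    _require_columns(pdf, _PATIENT_COLS, "patients.csv")
    _require_columns(ldf, _LESION_COLS, "lesions.csv")
    _require_columns(cdf, _CORE_COLS, "cores.csv")

    lesions_by_patient: dict[str, list[LesionRecord]] = {}
    for _, lrow in ldf.iterrows():
        masks = {}
        for attr in ("t2w_voi", "dwi_voi"):
            rel = _opt_str(lrow[attr])
            if rel is not None:
                arr, spacing = _read_nifti(os.path.join(path, rel))
                masks[attr] = VoxelMask(arr.round().astype(np.uint8), spacing)
            else:
                masks[attr] = None
        lesion = LesionRecord(
            lesion_id=str(lrow["lesion_id"]),
            patient_id=str(lrow["patient_id"]),
            pirads=int(lrow["pirads"]),
            zone=str(lrow["zone"]),
            sextants_overlapped=tuple(str(lrow["sextants_overlapped"]).split("|")),
            unet_lesion_score=_opt_float(lrow["unet_lesion_score"]),
            t2w_voi=masks["t2w_voi"],
            dwi_voi=masks["dwi_voi"],
        )
        lesions_by_patient.setdefault(lesion.patient_id, []).append(lesion)

    cores_by_patient: dict[str, list[CoreResult]] = {}
    for _, crow in cdf.iterrows():
        core = CoreResult(
            core_id=str(crow["core_id"]),
            patient_id=str(crow["patient_id"]),
            origin=str(crow["origin"]),
            lesion_id=_opt_str(crow["lesion_id"]),
            sextant=str(crow["sextant"]),
            isup_grade_group=int(crow["isup_grade_group"]),
        )
        cores_by_patient.setdefault(core.patient_id, []).append(core)

    exams = []
    for _, row in pdf.iterrows():
        pid = str(row["patient_id"])
        prob_map = prostate = None
        rel = _opt_str(row["prob_map"])
        if rel is not None:
            arr, spacing = _read_nifti(os.path.join(path, rel))
            prob_map = VoxelProbabilityMap(arr, spacing)
        rel = _opt_str(row["prostate_mask"])
        if rel is not None:
            arr, spacing = _read_nifti(os.path.join(path, rel))
            prostate = VoxelMask(arr.round().astype(np.uint8), spacing)
        exams.append(
            ExamRecord(
                patient_id=pid,
                time_index=int(row["time_index"]),
                referral=str(row["referral"]),
                psa=_opt_float(row["psa"]),
                unet_patient_score=float(row["unet_patient_score"]),
                unet_sextant_scores={s: float(row[f"unet_sextant_{s}"]) for s in SEXTANTS},
                lesions=lesions_by_patient.get(pid, []),
                cores=cores_by_patient.get(pid, []),
                prob_map=prob_map,
                prostate_mask=prostate,
            )
        )
    cohort = Cohort(exams)
    # referential integrity is an error on load (it breaks downstream joins);
    # all other invariant violations are reported by validate_cohort
    for exam in cohort:
        lesion_ids = {l.lesion_id for l in exam.lesions}
        for core in exam.cores:
            if core.origin == "targeted" and core.lesion_id not in lesion_ids:
                raise ReferentialError(
                    f"core {core.core_id!r} references absent lesion {core.lesion_id!r}"
                )
    return cohort
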