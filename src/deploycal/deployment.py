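"""Simulated prospective deployment with sliding look-back recalibration.

The fixed threshold set is calibrated once on the most recent *window* (default
300) examinations of the prior cohort.  The current cohort is then consumed in
batches (default 50): each examination is classified using only the dynamic
threshold set in force when it arrives; after every completed batch the dynamic
set is recalibrated on the most recent *window* examinations, which mix the
tail of the prior cohort with the current examinations seen so far.  A final
recalibration after the last examination is recorded but applied to nothing
(it shows where the thresholds would have moved next).  The limit set — the
hindsight optimum — is calibrated once on the full current cohort.

The remainder of the stream (259 = 5*50 + 9) is merged into the final applied
batch, so 259 examinations yield applied batches of 50, 50, 50, 50, 59 and
look-back windows whose prior-cohort share shrinks 300, 250, 200, 150, 100, 41.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .calibration import ThresholdSet, compute_thresholds, pirads_reference_points
from .cohort import SEXTANTS, Cohort, ExamRecord
from .dxstats import ConfusionCounts, holm, mcnemar_test, metrics_from_counts
from .errors import WindowError
from .fusion import GroundTruth, fuse, pirads_patient_category, pirads_sextant_category

__all__ = [
    "LookbackWindow",
    "ScheduleStep",
    "ThresholdSchedule",
    "DeploymentReport",
    "lookback_composition",
    "batch_sizes",
    "run_deployment",
]


@dataclass(frozen=True)
class LookbackWindow:
    """Composition of one look-back window: prior-cohort + current-cohort exams."""

    n_prior: int
    n_current: int

    def __post_init__(self):
        if self.n_prior < 0 or self.n_current < 0:
            raise WindowError("window composition counts must be non-negative")

    @property
    def size(self) -> int:
        return self.n_prior + self.n_current


def lookback_composition(step: int, prior_size: int, current_seen: int, window: int) -> LookbackWindow:
    """The most recent ``window`` exams after ``current_seen`` current exams:
    N_c = min(seen, window) from the current cohort, N_p = window - N_c from
    the prior cohort."""
    if prior_size + current_seen < window:
        raise WindowError(
            f"step {step}: only {prior_size + current_seen} exams available for a window of {window}"
        )
    n_current = min(current_seen, window)
    return LookbackWindow(n_prior=window - n_current, n_current=n_current)


def batch_sizes(n: int, batch: int) -> list[int]:
    """Applied batch sizes; the remainder is merged into the final batch."""
    if batch <= 0:
        raise ValueError("batch must be positive")
    q, r = divmod(n, batch)
    if q == 0:
        return [n] if n else []
    sizes = [batch] * q
    sizes[-1] += r
    return sizes


@dataclass(frozen=True)
class ScheduleStep:
    step: int
    thresholds: ThresholdSet
    window: LookbackWindow
    #: half-open index range of current-cohort exams predicted with these
    #: thresholds; empty for the final (never applied) readjustment
    applied_range: tuple[int, int]


@dataclass
class ThresholdSchedule:
    steps: list[ScheduleStep] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.steps)

    def __iter__(self):
        return iter(self.steps)

    def in_force(self, exam_index: int) -> ScheduleStep:
        for s in self.steps:
            lo, hi = s.applied_range
            if lo <= exam_index < hi:
                return s
        raise KeyError(f"no schedule step covers exam index {exam_index}")


@dataclass
class DeploymentReport:
    """All deployment outputs: per-batch metrics, look-back agreement, final
    patient/sextant performance tables, per-exam log, and the thresholds."""

    batch_table: pd.DataFrame
    lookback_table: pd.DataFrame
    patient_table: pd.DataFrame
    sextant_table: pd.DataFrame
    exam_log: pd.DataFrame
    fixed: ThresholdSet
    limit: ThresholdSet

    @property
    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "batch_table": self.batch_table,
            "lookback_table": self.lookback_table,
            "patient_table": self.patient_table,
            "sextant_table": self.sextant_table,
            "exam_log": self.exam_log,
        }


def _sens_spec(calls: np.ndarray, disease: np.ndarray) -> dict:
    c = ConfusionCounts.from_calls(calls, disease)
    m = metrics_from_counts(c)
    out = {}
    for name, metric in (("sens", m.sensitivity), ("spec", m.specificity)):
        out[f"{name}_pct"] = metric.pct if metric else None
        out[f"{name}_num"] = metric.numerator if metric else 0
        out[f"{name}_den"] = metric.denominator if metric else 0
    return out


def _resolve_truths(cohort: Cohort, truths) -> list[GroundTruth]:
    if truths is None:
        return [fuse(e) for e in cohort]
    if hasattr(truths, "truths"):  # TruthBundle
        return [truths[e.patient_id] for e in cohort]
    return list(truths)


def _final_table(
    exams: Sequence[ExamRecord],
    truths: Sequence[GroundTruth],
    dyn_t3: np.ndarray,
    dyn_t4: np.ndarray,
    fixed: ThresholdSet,
    limit: ThresholdSet,
    level: str,
) -> pd.DataFrame:
    """Table-5-style performance rows at one level (patient or sextant)."""
    if level == "patient":
        disease = np.array([t.patient_spc for t in truths], dtype=bool)
        scores = np.array([e.unet_patient_score for e in exams])
        pirads = np.array([pirads_patient_category(e) for e in exams])
        t3 = dyn_t3
        t4 = dyn_t4
    else:
        disease = np.array(
            [t.sextant_spc[s] for t in truths for s in SEXTANTS], dtype=bool
        )
        scores = np.array([e.unet_sextant_scores[s] for e in exams for s in SEXTANTS])
        pirads = np.array(
            [pirads_sextant_category(e)[s] for e in exams for s in SEXTANTS]
        )
        t3 = np.repeat(dyn_t3, len(SEXTANTS))
        t4 = np.repeat(dyn_t4, len(SEXTANTS))

    rules: dict[str, np.ndarray] = {
        "pirads>=3": pirads >= 3,
        "pirads>=4": pirads >= 4,
        "unet>=f3": scores >= fixed.t3,
        "unet>=f4": scores >= fixed.t4,
        "unet>=d3": scores >= t3,
        "unet>=d4": scores >= t4,
        "unet>=l3": scores >= limit.t3,
        "unet>=l4": scores >= limit.t4,
    }
    rows = []
    raw_p: list[float] = []
    for name, calls in rules.items():
        c = ConfusionCounts.from_calls(calls, disease)
        m = metrics_from_counts(c)
        row = {"level": level, "rule": name}
        for metric_name, metric in (
            ("sens", m.sensitivity),
            ("spec", m.specificity),
            ("ppv", m.ppv),
            ("npv", m.npv),
        ):
            if metric is None:
                row.update({f"{metric_name}_pct": None, f"{metric_name}_num": 0, f"{metric_name}_den": 0})
                continue
            lo, hi = metric.ci95
            row.update(
                {
                    f"{metric_name}_pct": metric.pct,
                    f"{metric_name}_num": metric.numerator,
                    f"{metric_name}_den": metric.denominator,
                    f"{metric_name}_ci_low": lo,
                    f"{metric_name}_ci_high": hi,
                }
            )
        row["p_sens_raw"] = row["p_spec_raw"] = None
        rows.append(row)

    # McNemar: dynamic rules vs their PI-RADS reference on the same units
    comparisons = [("unet>=d3", "pirads>=3"), ("unet>=d4", "pirads>=4")]
    for model_rule, ref_rule in comparisons:
        a, b = rules[model_rule], rules[ref_rule]
        for metric_name, subset in (("sens", disease), ("spec", ~disease)):
            if metric_name == "spec":
                a_s, b_s = ~a[subset], ~b[subset]  # correct negative calls
            else:
                a_s, b_s = a[subset], b[subset]
            disc_b = int((a_s & ~b_s).sum())
            disc_c = int((~a_s & b_s).sum())
            p = mcnemar_test(disc_b, disc_c)
            raw_p.append(p)
            for row in rows:
                if row["rule"] == model_rule:
                    row[f"p_{metric_name}_raw"] = p
    adj = holm(raw_p) if raw_p else []
    k = 0
    for model_rule, _ in comparisons:
        for metric_name in ("sens", "spec"):
            for row in rows:
                if row["rule"] == model_rule:
                    row[f"p_{metric_name}_holm"] = float(adj[k])
            k += 1
    return pd.DataFrame(rows)


def run_deployment(
    prior: Cohort,
    current: Cohort,
    prior_truth=None,
    current_truth=None,
    window: int = 300,
    batch: int = 50,
) -> tuple[DeploymentReport, ThresholdSchedule]:
    """Run the full simulated prospective deployment.

    ``prior_truth``/``current_truth`` may be TruthBundles, GroundTruth
    sequences, or None (ground truth is then fused from the biopsy cores).
    """
    prior_truths = _resolve_truths(prior, prior_truth)
    current_truths = _resolve_truths(current, current_truth)
    if len(prior) < window:
        raise WindowError(f"prior cohort has {len(prior)} exams; window needs {window}")

    prior_exams = list(prior)
    current_exams = list(current)
    n_current = len(current_exams)

    fixed = compute_thresholds(prior_exams[-window:], prior_truths[-window:], kind="fixed")
    limit = compute_thresholds(current_exams, current_truths, kind="limit")

    sizes = batch_sizes(n_current, batch)
    # window membership after `seen` current exams, mixing prior tail + current
    def window_exams(seen: int):
        comp = lookback_composition(0, len(prior_exams), seen, window)
        exams = prior_exams[len(prior_exams) - comp.n_prior :] + current_exams[
            seen - comp.n_current : seen
        ]
        truths = prior_truths[len(prior_truths) - comp.n_prior :] + current_truths[
            seen - comp.n_current : seen
        ]
        return comp, exams, truths

    steps: list[ScheduleStep] = []
    dynamic = ThresholdSet(fixed.t3, fixed.t4, kind="dynamic")
    seen = 0
    for k, size in enumerate(sizes):
        steps.append(
            ScheduleStep(
                step=k,
                thresholds=dynamic,
                window=lookback_composition(k, len(prior_exams), seen, window),
                applied_range=(seen, seen + size),
            )
        )
        seen += size
        comp, w_exams, w_truths = window_exams(seen)
        dynamic = compute_thresholds(w_exams, w_truths, kind="dynamic")
    # final readjustment: computed, applied to nothing
    steps.append(
        ScheduleStep(
            step=len(sizes),
            thresholds=dynamic,
            window=lookback_composition(len(sizes), len(prior_exams), seen, window),
            applied_range=(seen, seen),
        )
    )
    schedule = ThresholdSchedule(steps)

    # prospective per-exam calls under the in-force dynamic thresholds
    dyn_t3 = np.empty(n_current)
    dyn_t4 = np.empty(n_current)
    step_of_exam = np.empty(n_current, dtype=int)
    for s in steps[:-1]:
        lo, hi = s.applied_range
        dyn_t3[lo:hi] = s.thresholds.t3
        dyn_t4[lo:hi] = s.thresholds.t4
        step_of_exam[lo:hi] = s.step

    scores = np.array([e.unet_patient_score for e in current_exams])
    disease = np.array([t.patient_spc for t in current_truths], dtype=bool)
    pirads = np.array([pirads_patient_category(e) for e in current_exams])

    exam_log = pd.DataFrame(
        {
            "patient_id": [e.patient_id for e in current_exams],
            "time_index": [e.time_index for e in current_exams],
            "step": step_of_exam,
            "d3": dyn_t3,
            "d4": dyn_t4,
            "unet_patient_score": scores,
            "pirads": pirads,
            "spc": disease,
            "call_d3": scores >= dyn_t3,
            "call_d4": scores >= dyn_t4,
        }
    )

    batch_rows = []
    for s in steps[:-1]:
        lo, hi = s.applied_range
        sl = slice(lo, hi)
        row = {
            "step": s.step,
            "n": hi - lo,
            "f3": fixed.t3,
            "d3": s.thresholds.t3,
            "l3": limit.t3,
            "f4": fixed.t4,
            "d4": s.thresholds.t4,
            "l4": limit.t4,
        }
        rule_calls = {
            "pirads3": pirads[sl] >= 3,
            "unet_f3": scores[sl] >= fixed.t3,
            "unet_d3": scores[sl] >= s.thresholds.t3,
            "unet_l3": scores[sl] >= limit.t3,
            "pirads4": pirads[sl] >= 4,
            "unet_f4": scores[sl] >= fixed.t4,
            "unet_d4": scores[sl] >= s.thresholds.t4,
            "unet_l4": scores[sl] >= limit.t4,
        }
        for rule, calls in rule_calls.items():
            for key, val in _sens_spec(calls, disease[sl]).items():
                row[f"{rule}_{key}"] = val
        batch_rows.append(row)
    batch_table = pd.DataFrame(batch_rows)

    lookback_rows = []
    for s in steps:
        comp, w_exams, w_truths = window_exams(
            s.applied_range[0] if s.step < len(sizes) else n_current
        )
        w_scores = np.array([e.unet_patient_score for e in w_exams])
        w_disease = np.array([t.patient_spc for t in w_truths], dtype=bool)
        w_pirads = np.array([pirads_patient_category(e) for e in w_exams])
        row = {
            "step": s.step,
            "n_prior": comp.n_prior,
            "n_current": comp.n_current,
            "n": comp.size,
            "d3": s.thresholds.t3,
            "d4": s.thresholds.t4,
        }
        for rule, calls in (
            ("pirads3", w_pirads >= 3),
            ("unet_d3", w_scores >= s.thresholds.t3),
            ("pirads4", w_pirads >= 4),
            ("unet_d4", w_scores >= s.thresholds.t4),
        ):
            for key, val in _sens_spec(calls, w_disease).items():
                row[f"{rule}_{key}"] = val
        lookback_rows.append(row)
    lookback_table = pd.DataFrame(lookback_rows)

    patient_table = _final_table(
        current_exams, current_truths, dyn_t3, dyn_t4, fixed, limit, level="patient"
    )
    sextant_table = _final_table(
        current_exams, current_truths, dyn_t3, dyn_t4, fixed, limit, level="sextant"
    )

    report = DeploymentReport(
        batch_table=batch_table,
        lookback_table=lookback_table,
        patient_table=patient_table,
        sextant_table=sextant_table,
        exam_log=exam_log,
        fixed=fixed,
        limit=limit,
    )
    return report, schedule
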