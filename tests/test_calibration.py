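import numpy as np
import pytest

from deploycal.calibration import (
    RocCurve,
    ThresholdSet,
    WorkingPoint,
    compute_thresholds,
    match_threshold,
    pirads_reference_points,
    roc_points,
)
from deploycal.errors import DegenerateInputError
from deploycal.synthetic import default_paper_config, generate_cohort

from conftest import make_exam, truths_of


def brute_force_roc(scores, labels):
    """Independent oracle: evaluate the confusion matrix at every candidate."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=bool)
    thresholds = sorted(set(scores)) + [max(scores) + 1.0]
    points = []
    for t in thresholds:
        pred = scores >= t
        sens = (pred & labels).sum() / labels.sum()
        spec = (~pred & ~labels).sum() / (~labels).sum()
        points.append((t, sens, spec))
    return points


def test_perfect_separation_curve():
    roc = roc_points([0.9, 0.1], [True, False])
    assert list(roc.thresholds) == [0.1, 0.9, 1.9]
    assert list(roc.sensitivity) == [1.0, 1.0, 0.0]
    assert list(roc.specificity) == [0.0, 1.0, 1.0]


def test_all_equal_scores_degenerate_curve():
    roc = roc_points([0.5, 0.5, 0.5], [True, False, True])
    assert len(roc) == 2  # all-positive and the all-negative sentinel
    assert roc.sensitivity[0] == 1.0 and roc.specificity[0] == 0.0
    assert roc.sensitivity[1] == 0.0 and roc.specificity[1] == 1.0


def test_single_class_labels_rejected():
    with pytest.raises(DegenerateInputError):
        roc_points([0.1, 0.9], [True, True])


@pytest.mark.parametrize("seed", range(5))
def test_roc_matches_brute_force_oracle(seed):
    rng = np.random.default_rng(seed)
    scores = rng.choice(np.round(rng.random(12), 2), size=40)  # force ties
    labels = rng.random(40) < 0.4
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    roc = roc_points(scores, labels)
    oracle = brute_force_roc(scores, labels)
    assert len(roc) == len(oracle)
    for i, (t, sens, spec) in enumerate(oracle):
        assert roc.thresholds[i] == pytest.approx(t)
        assert roc.sensitivity[i] == pytest.approx(sens)
        assert roc.specificity[i] == pytest.approx(spec)


def test_roc_invariants_on_random_instances():
    rng = np.random.default_rng(11)
    for _ in range(10):
        scores = rng.random(60)
        labels = rng.random(60) < 0.5
        if labels.all() or not labels.any():
            labels[0] = ~labels[0]
        roc = roc_points(scores, labels)  # RocCurve validates monotonicity
        assert (np.diff(roc.thresholds) > 0).all()


def test_match_exact_point_and_tie_break():
    roc = RocCurve(
        thresholds=np.array([0.1, 0.5, 0.9]),
        sensitivity=np.array([1.0, 0.6, 0.2]),
        specificity=np.array([0.2, 0.6, 1.0]),
    )
    assert match_threshold(roc, WorkingPoint(0.6, 0.6)) == 0.5
    # (1.0, 0.2) and (0.2, 1.0) are equidistant from (0.6, 0.6) once the middle
    # point is removed: the smaller threshold must win
    roc2 = RocCurve(
        thresholds=np.array([0.1, 0.9]),
        sensitivity=np.array([1.0, 0.2]),
        specificity=np.array([0.2, 1.0]),
    )
    assert match_threshold(roc2, WorkingPoint(0.6, 0.6)) == 0.1


@pytest.mark.parametrize("seed", range(5))
def test_match_equals_exhaustive_scan(seed):
    rng = np.random.default_rng(100 + seed)
    scores = rng.random(30)
    labels = rng.random(30) < 0.5
    if labels.all() or not labels.any():
        labels[0] = ~labels[0]
    roc = roc_points(scores, labels)
    target = WorkingPoint(rng.random(), rng.random())
    best = match_threshold(roc, target)
    d2 = (roc.sensitivity - target.sensitivity) ** 2 + (roc.specificity - target.specificity) ** 2
    i = list(roc.thresholds).index(best)
    assert np.all(d2[i] <= d2 + 1e-15)
    assert best in roc.thresholds  # no interpolation ever


def test_threshold_crossing_warns_but_is_allowed():
    with pytest.warns(UserWarning, match="t3"):
        ThresholdSet(t3=0.5, t4=0.3, kind="fixed")


def test_perfect_surrogate_recovers_reference_point():
    exams, truths = [], []
    from deploycal.fusion import GroundTruth

    for i in range(20):
        pirads4 = i % 2 == 0
        exams.append(
            make_exam(
                f"P{i}", i,
                pirads_lesions=[(4 if pirads4 else 2, ("LB",))],
                patient_score=1.0 if pirads4 else 0.0,
            )
        )
        truths.append(GroundTruth(patient_spc=i % 4 == 0, sextant_spc={}, lesion_spc={}))
    ref = pirads_reference_points(exams, truths)
    tset = compute_thresholds(exams, truths, kind="fixed", reference=ref)
    scores = np.array([e.unet_patient_score for e in exams])
    disease = np.array([t.patient_spc for t in truths])
    calls = scores >= tset.t4
    sens = (calls & disease).sum() / disease.sum()
    spec = (~calls & ~disease).sum() / (~disease).sum()
    assert 0.0 < tset.t4 <= 1.0
    assert (sens, spec) == (ref[4].sensitivity, ref[4].specificity)


def test_calibration_matches_pirads_reference_on_synthetic_windows():
    """Over fixed-seed 300-exam windows the matched working points track the
    PI-RADS reference to within the sampling noise of such a window: average
    axis deviation below 0.05 (a single window can stray further when the
    empirical ROC happens to pass no closer to the reference point)."""
    devs = []
    for seed in range(1, 7):
        cohort, bundle = generate_cohort(default_paper_config(n_patients=300, seed=seed))
        exams = list(cohort)
        truths = truths_of(cohort, bundle)
        ref = pirads_reference_points(exams, truths)
        tset = compute_thresholds(exams, truths, kind="fixed")
        scores = np.array([e.unet_patient_score for e in exams])
        disease = np.array([t.patient_spc for t in truths])
        for t, cutoff in ((tset.t3, 3), (tset.t4, 4)):
            calls = scores >= t
            sens = (calls & disease).sum() / disease.sum()
            spec = (~calls & ~disease).sum() / (~disease).sum()
            devs.append(abs(sens - ref[cutoff].sensitivity))
            devs.append(abs(spec - ref[cutoff].specificity))
    assert np.mean(devs) < 0.05
    assert max(devs) < 0.1


def test_calibration_is_deterministic_and_permutation_invariant(synthetic_cohort_300):
    cohort, bundle = synthetic_cohort_300
    exams = list(cohort)
    truths = truths_of(cohort, bundle)
    a = compute_thresholds(exams, truths)
    b = compute_thresholds(exams, truths)
    assert a == b
    rng = np.random.default_rng(1)
    order = rng.permutation(len(exams))
    shuffled = compute_thresholds([exams[i] for i in order], [truths[i] for i in order])
    assert shuffled == a
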