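"""Synthetic cohort generation with the statistical structure of the study.

Each patient draws a disease state (sPC, prevalence 108/259) and a bivariate
standard-normal latent pair (z_r, z_s) with correlation 0.6.  z_r drives the
radiologist: class-conditional cutpoints on z_r yield the PI-RADS index
category 1-5 (1 = no lesion), calibrated so the patient-level PI-RADS >= 3 and
>= 4 operating points sit at (sens 98%, spec 17%) and (84%, 58%).  z_s drives
the model score through a Gaussian copula into class-conditional beta
distributions chosen so the score ROC passes through those same two operating
points (the deployed classifier tracked the radiologists closely).

Lesions, sextant anatomy, and biopsy cores are then generated consistently:
diseased patients carry at least one sPC lesion (or, for the rare no-lesion
diseased patient, sPC found only by systematic cores), targeted and systematic
cores detect sPC with configurable per-core probabilities, and the intended
ground truth is recorded alongside so that histology fusion of the generated
cores can be cross-checked against it.

An optional drift mechanism shifts the category-3 cutpoint linearly per batch,
emulating a slowly liberalizing reading style for the indeterminate category:
positive drift lowers the cutpoint, so PI-RADS >= 3 specificity falls over
time while the model score distribution stays put.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .cohort import SEXTANTS, Cohort, CoreResult, ExamRecord, LesionRecord
from .errors import ConfigError, GeometryError
from .fusion import GroundTruth
from .segmentation import VoxelMask, VoxelProbabilityMap

__all__ = [
    "GeneratorConfig",
    "TruthBundle",
    "default_paper_config",
    "generate_cohort",
    "apply_drift",
    "generate_drifting_stream",
    "generate_voxel_phantom",
    "DEFAULT_SEED",
]

DEFAULT_SEED = 20170101

# Class-conditional P(category >= k) for k = 2..5 on the radiologist latent.
# The >=3 / >=4 entries are the target operating points; >=2 / >=5 shape the
# index-lesion marginals (roughly 20/259 no-lesion and 50/259 category-5 men).
_EXCEEDANCE_SPC = (0.995, 0.98, 0.84, 0.32)
_EXCEEDANCE_BENIGN = (0.90, 0.83, 0.42, 0.102)

# Beta(a, b) score families per class, solved so the score ROC passes through
# (sens 0.98, spec 0.17) and (sens 0.84, spec 0.58).
_SCORE_PARAMS = ((2.667074, 1.908179), (2.0, 4.0))


def _cutpoints(exceedance: tuple[float, ...]) -> tuple[float, ...]:
    return tuple(float(-stats.norm.ppf(p)) for p in exceedance)


@dataclass
class GeneratorConfig:
    """Calibration of the synthetic cohort; defaults are the study conditions."""

    n_patients: int = 259
    prevalence: float = 108 / 259
    latent_correlation: float = 0.6
    #: ((a+, b+), (a-, b-)) beta shapes for the patient score given sPC+/sPC-.
    score_params: tuple[tuple[float, float], tuple[float, float]] = _SCORE_PARAMS
    #: per-class ascending cutpoints on the radiologist latent for categories 2..5
    pirads_cutpoints: dict[str, tuple[float, ...]] = field(
        default_factory=lambda: {
            "spc": _cutpoints(_EXCEEDANCE_SPC),
            "benign": _cutpoints(_EXCEEDANCE_BENIGN),
        }
    )
    #: count distributions (value -> probability)
    lesions_per_patient: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.30, 3: 0.15, 4: 0.05}
    )
    sextants_per_lesion: dict[int, float] = field(
        default_factory=lambda: {1: 0.50, 2: 0.35, 3: 0.15}
    )
    #: per-core probability that a core sampling an sPC-bearing site is ISUP >= 2
    systematic_detection_prob: float = 0.65
    targeted_detection_prob: float = 0.80
    #: probability a non-index lesion of a diseased patient harbors sPC
    secondary_lesion_spc_prob: float = 0.05
    #: probability an off-lesion sextant of a diseased patient harbors sPC
    extra_spc_sextant_prob: float = 0.08
    targeted_cores_per_lesion: int = 4
    systematic_cores_per_sextant: int = 4
    #: beta shapes for sextant scores given the sextant's sPC state
    sextant_score_params: tuple[tuple[float, float], tuple[float, float]] = ((2.2, 2.5), (1.3, 8.0))
    #: weight coupling sextant/lesion score latents to the patient score latent
    sextant_latent_weight: float = 0.4
    #: ISUP grade group distribution of significant cores (Table-1-like mix)
    isup_distribution: dict[int, float] = field(
        default_factory=lambda: {2: 0.61, 3: 0.17, 4: 0.065, 5: 0.155}
    )
    #: per-core probability that a benign core shows ISUP grade group 1
    benign_isup1_prob: float = 0.012
    referral_probs: dict[str, float] = field(
        default_factory=lambda: {
            "biopsy_naive": 0.56,
            "previously_biopsied": 0.21,
            "active_surveillance": 0.23,
        }
    )
    #: optional linear per-batch downward shift of the category-3 cutpoint
    drift: float | None = None
    seed: int = DEFAULT_SEED

    def validate(self) -> None:
        if self.n_patients < 0:
            raise ConfigError("n_patients must be non-negative")
        if not 0.0 < self.prevalence < 1.0:
            raise ConfigError("prevalence must lie in (0, 1)")
        if not -1.0 <= self.latent_correlation <= 1.0:
            raise ConfigError("latent_correlation must lie in [-1, 1]")
        for cls in ("spc", "benign"):
            cuts = self.pirads_cutpoints[cls]
            if len(cuts) != 4 or any(b <= a for a, b in zip(cuts, cuts[1:])):
                raise ConfigError(f"{cls} cutpoints must be 4 strictly increasing values")
        for name in (
            "systematic_detection_prob",
            "targeted_detection_prob",
            "secondary_lesion_spc_prob",
            "extra_spc_sextant_prob",
            "benign_isup1_prob",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigError(f"{name} must lie in [0, 1]")
        for name in ("lesions_per_patient", "sextants_per_lesion", "isup_distribution", "referral_probs"):
            dist = getattr(self, name)
            total = sum(dist.values())
            if abs(total - 1.0) > 1e-9 or any(p < 0 for p in dist.values()):
                raise ConfigError(f"{name} must be a probability distribution (sums to {total})")
        for pair in (*self.score_params, *self.sextant_score_params):
            if pair[0] <= 0 or pair[1] <= 0:
                raise ConfigError("beta shape parameters must be positive")


@dataclass
class TruthBundle:
    """Ground truth known by construction, keyed by patient_id."""

    truths: dict[str, GroundTruth] = field(default_factory=dict)

    def __getitem__(self, patient_id: str) -> GroundTruth:
        return self.truths[patient_id]

    def __len__(self) -> int:
        return len(self.truths)


def default_paper_config(n_patients: int = 259, seed: int = DEFAULT_SEED) -> GeneratorConfig:
    """The shipped calibration matching the study's patient-level marginals."""
    return GeneratorConfig(n_patients=n_patients, seed=seed)


def apply_drift(config: GeneratorConfig, batch_index: int) -> GeneratorConfig:
    """Return a config with the category-3 cutpoint lowered by drift*batch_index.

    Positive drift makes category->=3 calls more liberal over time (more
    lesions rated at least 3), so specificity at the >=3 cutoff decreases.
    """
    if config.drift is None:
        raise ConfigError("drift is not specified in this config")
    shift = config.drift * batch_index
    new_cuts = {}
    for cls, cuts in config.pirads_cutpoints.items():
        c2, c3, c4, c5 = cuts
        c3 = c3 - shift
        if not c2 < c3 < c4:
            raise ConfigError(
                f"drift shift {shift} pushes the {cls} category-3 cutpoint past its neighbors"
            )
        new_cuts[cls] = (c2, c3, c4, c5)
    return dataclasses.replace(config, pirads_cutpoints=new_cuts)


def _choice_dist(rng: np.random.Generator, dist: dict, size: int) -> np.ndarray:
    keys = np.array(list(dist.keys()))
    probs = np.array(list(dist.values()), dtype=float)
    return rng.choice(keys, size=size, p=probs / probs.sum())


def generate_cohort(
    config: GeneratorConfig,
    *,
    start_index: int = 0,
    id_prefix: str = "P",
) -> tuple[Cohort, TruthBundle]:
    """Generate a cohort and its by-construction ground truth, reproducibly.

    ``start_index``/``id_prefix`` allow concatenating independently generated
    streams (e.g. a prior and a current cohort) with unique ids and strictly
    increasing time indices.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    if n == 0:
        return Cohort([]), TruthBundle({})

    rho = config.latent_correlation
    diseased = rng.random(n) < config.prevalence
    z_r = rng.standard_normal(n)
    z_s = rho * z_r + np.sqrt(max(0.0, 1.0 - rho**2)) * rng.standard_normal(n)
    u = stats.norm.cdf(z_s)
    (a_pos, b_pos), (a_neg, b_neg) = config.score_params
    patient_score = np.where(
        diseased,
        stats.beta.ppf(u, a_pos, b_pos),
        stats.beta.ppf(u, a_neg, b_neg),
    )

    cuts_spc = np.array(config.pirads_cutpoints["spc"])
    cuts_ben = np.array(config.pirads_cutpoints["benign"])
    cat = np.where(
        diseased,
        1 + np.searchsorted(cuts_spc, z_r, side="right"),
        1 + np.searchsorted(cuts_ben, z_r, side="right"),
    )

    referrals = _choice_dist(rng, config.referral_probs, n)
    psa = np.exp(rng.normal(np.log(7.2), 0.5, size=n))

    isup_keys = np.array(list(config.isup_distribution.keys()))
    isup_probs = np.array(list(config.isup_distribution.values()), dtype=float)
    isup_probs = isup_probs / isup_probs.sum()
    lam = config.sextant_latent_weight
    (sa_pos, sb_pos), (sa_neg, sb_neg) = config.sextant_score_params

    # First pass: draw the discrete anatomy and core outcomes per patient,
    # deferring all beta transforms to one vectorized pass at the end.
    exams_raw = []
    sextant_u: list[float] = []
    sextant_truth: list[bool] = []
    lesion_u: list[float] = []
    lesion_truth: list[bool] = []
    for i in range(n):
        pid = f"{id_prefix}{start_index + i:06d}"
        d = bool(diseased[i])
        category = int(cat[i])

        lesions = []
        lesion_is_spc: list[bool] = []
        if category >= 2:
            n_les = int(_choice_dist(rng, config.lesions_per_patient, 1)[0])
            for j in range(n_les):
                pirads = category if j == 0 else int(rng.integers(2, category + 1))
                k = int(_choice_dist(rng, config.sextants_per_lesion, 1)[0])
                sextants = tuple(
                    SEXTANTS[idx] for idx in sorted(rng.choice(6, size=k, replace=False))
                )
                zone = "PZ" if rng.random() < 0.71 else "TZ"
                lesions.append(
                    LesionRecord(
                        lesion_id=f"{pid}-L{j}",
                        patient_id=pid,
                        pirads=pirads,
                        zone=zone,
                        sextants_overlapped=sextants,
                    )
                )
                if d:
                    spc = j == 0 or rng.random() < config.secondary_lesion_spc_prob
                else:
                    spc = False
                lesion_is_spc.append(spc)

        spc_sextants: set[str] = set()
        if d:
            for lesion, spc in zip(lesions, lesion_is_spc):
                if spc:
                    spc_sextants.update(lesion.sextants_overlapped)
            for s in SEXTANTS:
                if s not in spc_sextants and rng.random() < config.extra_spc_sextant_prob:
                    spc_sextants.add(s)
            if not spc_sextants and not any(lesion_is_spc):
                # diseased patient without lesions: sPC reachable only by
                # systematic cores in one randomly placed sextant
                spc_sextants.add(SEXTANTS[int(rng.integers(6))])

        def _sig_grade() -> int:
            return int(rng.choice(isup_keys, p=isup_probs))

        def _benign_grade() -> int:
            return 1 if rng.random() < config.benign_isup1_prob else 0

        cores = []
        truth_lesions: dict[str, bool] = {}
        truth_sextants = {s: False for s in SEXTANTS}
        cid = 0
        for lesion, spc in zip(lesions, lesion_is_spc):
            hits = rng.random(config.targeted_cores_per_lesion) < config.targeted_detection_prob
            if spc and not hits.any():
                hits[0] = True  # the designated sPC lesion is always confirmed
            any_sig = False
            for hit in hits:
                sig = bool(spc and hit)
                any_sig |= sig
                cores.append(
                    CoreResult(
                        core_id=f"{pid}-C{cid}",
                        patient_id=pid,
                        origin="targeted",
                        lesion_id=lesion.lesion_id,
                        sextant=lesion.sextants_overlapped[
                            int(rng.integers(len(lesion.sextants_overlapped)))
                        ],
                        isup_grade_group=_sig_grade() if sig else _benign_grade(),
                    )
                )
                cid += 1
            truth_lesions[lesion.lesion_id] = any_sig
            if any_sig:
                for s in lesion.sextants_overlapped:
                    truth_sextants[s] = True

        forced_systematic = d and not any(truth_lesions.values())
        for s in SEXTANTS:
            bearing = s in spc_sextants
            hits = rng.random(config.systematic_cores_per_sextant) < config.systematic_detection_prob
            if forced_systematic and bearing and s == sorted(spc_sextants)[0] and not hits.any():
                hits[0] = True
            for hit in hits:
                sig = bool(bearing and hit)
                if sig:
                    truth_sextants[s] = True
                cores.append(
                    CoreResult(
                        core_id=f"{pid}-C{cid}",
                        patient_id=pid,
                        origin="systematic",
                        lesion_id=None,
                        sextant=s,
                        isup_grade_group=_sig_grade() if sig else _benign_grade(),
                    )
                )
                cid += 1

        # latent draws for sextant and lesion scores (transformed after loop)
        eps = rng.standard_normal(6)
        z_sx = lam * z_s[i] + np.sqrt(1 - lam**2) * eps
        sextant_u.extend(stats.norm.cdf(z_sx))
        sextant_truth.extend(truth_sextants[s] for s in SEXTANTS)
        for lesion in lesions:
            z_l = lam * z_s[i] + np.sqrt(1 - lam**2) * rng.standard_normal()
            lesion_u.append(stats.norm.cdf(z_l))
            lesion_truth.append(truth_lesions[lesion.lesion_id])

        truth = GroundTruth(
            patient_spc=any(truth_sextants.values()) or any(truth_lesions.values()),
            sextant_spc=truth_sextants,
            lesion_spc=truth_lesions,
        )
        exams_raw.append((pid, i, lesions, cores, truth))

    sextant_u_arr = np.asarray(sextant_u)
    sextant_truth_arr = np.asarray(sextant_truth, dtype=bool)
    sextant_scores = np.where(
        sextant_truth_arr,
        stats.beta.ppf(sextant_u_arr, sa_pos, sb_pos),
        stats.beta.ppf(sextant_u_arr, sa_neg, sb_neg),
    )
    if lesion_u:
        lesion_u_arr = np.asarray(lesion_u)
        lesion_truth_arr = np.asarray(lesion_truth, dtype=bool)
        lesion_scores = np.where(
            lesion_truth_arr,
            stats.beta.ppf(lesion_u_arr, a_pos, b_pos),
            stats.beta.ppf(lesion_u_arr, a_neg, b_neg),
        )
    else:
        lesion_scores = np.empty(0)

    exams = []
    truths: dict[str, GroundTruth] = {}
    s_ofs = l_ofs = 0
    for pid, i, lesions, cores, truth in exams_raw:
        for lesion in lesions:
            lesion.unet_lesion_score = float(lesion_scores[l_ofs])
            l_ofs += 1
        scores6 = {s: float(sextant_scores[s_ofs + k]) for k, s in enumerate(SEXTANTS)}
        s_ofs += 6
        exams.append(
            ExamRecord(
                patient_id=pid,
                time_index=start_index + i,
                referral=str(referrals[i]),
                psa=float(psa[i]),
                unet_patient_score=float(patient_score[i]),
                unet_sextant_scores=scores6,
                lesions=lesions,
                cores=cores,
            )
        )
        truths[pid] = truth
    return Cohort(exams), TruthBundle(truths)


def generate_drifting_stream(
    config: GeneratorConfig,
    n_batches: int,
    batch_size: int,
    *,
    start_index: int = 0,
    id_prefix: str = "D",
) -> tuple[Cohort, TruthBundle]:
    """Concatenate per-batch cohorts with the category-3 cutpoint drifting.

    Batch k is generated under ``apply_drift(config, k)`` with seed ``seed+k``,
    emulating a radiologist population whose category-3 behavior moves linearly
    while the model score distribution stays stationary.
    """
    exams: list[ExamRecord] = []
    truths: dict[str, GroundTruth] = {}
    for k in range(n_batches):
        cfg_k = apply_drift(config, k)
        cfg_k = dataclasses.replace(cfg_k, n_patients=batch_size, seed=config.seed + k)
        cohort_k, truth_k = generate_cohort(
            cfg_k, start_index=start_index + k * batch_size, id_prefix=f"{id_prefix}{k}_"
        )
        exams.extend(cohort_k.exams)
        truths.update(truth_k.truths)
    return Cohort(exams), TruthBundle(truths)


# ---------------------------------------------------------------------------
# Voxel phantoms for the segmentation-overlap analysis
# ---------------------------------------------------------------------------


def generate_voxel_phantom(
    lesion_specs: list[dict],
    grid: tuple[int, int, int],
    seed: int = DEFAULT_SEED,
) -> tuple[VoxelProbabilityMap, list[VoxelMask]]:
    """Build a probability map of Gaussian blobs plus jittered ellipsoid VOIs.

    Each lesion spec is a dict with ``center`` (voxel triple), ``sigma`` (blob
    scale), ``amplitude`` (peak probability, <= 1), optional ``voi_offset``
    (triple added to the center for the manual VOI) and ``voi_radii`` (ellipsoid
    semi-axes, default 2*sigma).  Overlap statistics of the phantom are exactly
    countable, which makes it the fixture generator for Dice testing.
    """
    grid = tuple(int(g) for g in grid)
    coords = np.indices(grid).astype(float)
    total = np.zeros(grid, dtype=float)
    vois: list[VoxelMask] = []
    for spec in lesion_specs:
        center = np.asarray(spec["center"], dtype=float)
        if (center < 0).any() or (center >= np.asarray(grid)).any():
            raise GeometryError(f"lesion center {tuple(center)} outside grid {grid}")
        sigma = float(spec.get("sigma", 3.0))
        amplitude = float(spec.get("amplitude", 0.9))
        d2 = sum((coords[k] - center[k]) ** 2 for k in range(3))
        total += amplitude * np.exp(-d2 / (2.0 * sigma**2))
        voi_center = center + np.asarray(spec.get("voi_offset", (0, 0, 0)), dtype=float)
        radii = np.asarray(spec.get("voi_radii", (2 * sigma,) * 3), dtype=float)
        ell = sum(((coords[k] - voi_center[k]) / radii[k]) ** 2 for k in range(3)) <= 1.0
        vois.append(VoxelMask(ell.astype(np.uint8)))
    return VoxelProbabilityMap(np.clip(total, 0.0, 1.0)), vois
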