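# Methods

## Setting and notation

One examination is one patient visit carrying: the radiologist's PI-RADS
lesions (ordinal categories 2–5; a patient's category is the index — maximum —
lesion, with 1 as the sentinel for "no lesion"); biopsy cores, each with an
ISUP grade group 0–5 (0 = benign); and the classifier's continuous
tumor-probability scores at patient, sextant, and lesion level, optionally
backed by a 3-D probability map (in which case the patient score equals the
map maximum inside the prostate mask).  Clinically significant prostate
cancer (sPC) is ISUP grade group ≥ 2.  The six sextants are
{left, right} × {base, mid, apex}, stored as two-letter codes (LB, LM, LA,
RB, RM, RA).  All binarizations are inclusive: a category or score is
positive at cutoff `c` iff value ≥ c.

## Histology fusion

The ground-truth reference fuses targeted and systematic histology under a
maximum-evidence rule:

* a lesion is sPC-positive iff any of its targeted cores is significant;
* a sextant is sPC-positive iff any systematic core located in it is
  significant, or a significant targeted core belongs to a lesion overlapping
  it;
* the patient is positive iff any core is significant.

Assumption: a significant targeted core credits *every* sextant its lesion
overlaps, not only the core's own position.  The alternative (credit only the
core's sextant) would weaken sextant labels for multi-sextant lesions; the
chosen rule uses all available histological information, including sPC found
outside radiologist lesions by the systematic saturation cores.  Raising any
core's grade can never flip a positive label to negative (monotonicity), which
is enforced by property tests.

## Threshold calibration

The ROC is built over the candidate thresholds = the unique observed scores
plus one sentinel above the maximum (the all-negative classifier); no
interpolation between candidates is ever performed, so a calibrated threshold
is always an observed score.  The reference working points are the
radiologist's empirical (sensitivity, specificity) at PI-RADS ≥ 3 and ≥ 4 *on
the same examinations* being calibrated on.  The matched threshold minimizes
the Euclidean distance in (sensitivity, specificity) space; ties break toward
the smaller threshold because in this screening context sensitivity is the
clinically protective axis.  Calibration is always patient-based, even when
the resulting thresholds are later applied to sextant and lesion scores.
`t3 > t4` is possible in principle (nothing in the procedure forbids
crossing) and only triggers a warning.

## Deployment scheme

* **Fixed set (f3/f4):** calibrated once on the most recent `window`
  (default 300) examinations of the prior cohort, by time index.
* **Dynamic set (d3/d4):** step 0 equals the fixed set and is applied to the
  first batch (default 50 exams).  After each completed batch the set is
  recalibrated on the most recent `window` examinations — `N_c = min(seen,
  window)` current exams plus `N_p = window − N_c` prior exams.  Every exam is
  classified prospectively, using only the set in force when it arrives; a
  final recalibration after the last exam is recorded but applied to nothing.
  The stream remainder is merged into the final batch (259 exams at batch 50
  give applied batches 50, 50, 50, 50, 59 and prior shares 300, 250, 200,
  150, 100, 41).
* **Limit set (l3/l4):** the hindsight optimum, calibrated once on the full
  current cohort; it is the yardstick for how well the dynamic scheme could
  possibly do.

The PI-RADS reference working points are recomputed on each look-back window
(so the dynamic thresholds chase the radiologists' *current* behavior, which
is the point of the scheme).  On a stationary stream the final dynamic set
equals the limit set exactly when the final window coincides with the current
cohort (current length = window); when the final window still contains
prior-cohort exams (as with a 259-exam stream), the final dynamic thresholds
land within a few candidate-score steps of the limit values — the package
tests this as agreement of the realized working points to within 0.05 per
axis rather than as single-grid-step threshold agreement, which is not a true
invariant of overlapping finite windows.

## Paired statistics

* **Proportions** carry exact integer numerator/denominator, Clopper–Pearson
  95 % CIs (chosen for exact reproducibility), and half-up integer-percent
  rendering (106/108 → 98 %).  Zero-denominator metrics are undefined, never
  rendered as 0.
* **McNemar:** exact two-sided binomial on the discordant counts (b, c) when
  b + c ≤ 25 (p = min(1, 2·P(X ≤ min(b,c)) with X ~ Bin(b+c, ½))), otherwise
  the continuity-corrected χ² = (|b−c|−1)²/(b+c).  The switch point 25 is
  standard small-sample practice; the two variants agree to < 0.01 at
  b + c = 200.
* **Relative predictive values:** for two binary tests A and B on the same
  units, rPPV = PPV_A/PPV_B is tested with a Wald statistic on log rPPV.  The
  variance follows from the delta method applied to the 8-cell paired
  multinomial; because the gradient of the log-ratio is centered, it reduces
  to Σ_k n_k·a_k² with a_k the per-cell gradient.  rNPV is handled
  symmetrically on the negative calls and non-diseased units.  When both
  margins agree cell-by-cell the variance is zero and the ratio exactly 1;
  p is then 1 by convention.  Degenerate margins (no positive calls, or a
  zero PPV/NPV numerator) raise an error naming the margin.  At table totals
  near 50 the delta-method standard error differs from a 20 000-replicate
  bootstrap standard error by a visible higher-order term (p-value gaps up to
  ~0.07 on adversarially small tables); the two agree to < 0.02 on tables
  with cells of 20–60.  The delta method is the field standard (it is the
  approach behind the commonly used R implementation) and is what the package
  ships.
* **Holm:** step-down adjustment, applied per table family (one family per
  performance table level; one family per co-occurrence level across all
  conjunction-vs-baseline tests).  The exact family composition behind
  published adjusted p-values is generally not recoverable, so raw p-values
  are the primary testable quantity and published adjusted values act as
  upper bounds.

## Conjunction analysis

The conjunction rule calls a unit positive only when the radiologist rule and
the model rule both do.  Levels: patients (index category vs patient score),
sextants (max overlapping lesion category vs sextant score), lesions
(lesion category vs lesion score; when only a probability map exists, the
lesion score is the map maximum inside the union of the lesion's T2w and DWI
VOIs).  Lesion-level analysis is conditioned on clinically identified
lesions, so there is no model-alone lesion rule (the model's own candidate
lesions are a different unit universe).  Set-theoretically, conjunction
positives are a subset of each rule's positives and conjunction TP ≤ each
rule's TP; conjunction PPV is *not* guaranteed to dominate either single-rule
PPV and is not asserted.

## Segmentation overlap

Model lesions are the 26-connected components of {map ≥ threshold} inside the
prostate mask, discarding components below `min_voxels` (default 10; both
choices are exposed because no canonical values exist), ordered by size
descending with lexicographic-first-voxel tie-break for determinism.  Each
manual VOI is scored against the union of the derived components that
intersect it; lesions hit by no component score 0 and are flagged, and the
cohort mean is reported both including and excluding such zero-overlap
lesions, because either convention is defensible and they can differ
materially.  "Combined" mode uses the union of the T2w and DWI VOIs (the
least-assumption reading of combining two observer segmentations).

## The synthetic generator

Each patient draws disease ~ Bernoulli(108/259) and a bivariate standard
normal latent (z_r, z_s) with correlation 0.6 (a moderate radiologist–model
agreement; at 0 the PI-RADS category and the score are conditionally
independent given disease, which is property-tested).  z_r maps to the
PI-RADS index category through class-conditional cutpoints whose exceedance
probabilities at ≥ 3/≥ 4 are exactly the target operating points
(sens 98 %/spec 17 % and 84 %/58 %); the ≥ 2 and ≥ 5 exceedances (0.995/0.32
diseased, 0.90/0.102 non-diseased) were chosen once to approximate the
index-lesion marginals of a 259-man cohort (≈ 20 no-lesion and ≈ 50
category-5 men) while leaving a wide corridor below the category-3 cutpoint
so drift cannot collide with category 2.  Φ(z_s) feeds class-conditional beta
score distributions — Beta(2.667, 1.908) for sPC+ and Beta(2, 4) for sPC− —
solved (once, with a root finder) so the score ROC passes exactly through
both radiologist operating points; the implied AUC is ≈ 0.81.

Anatomy and histology: lesion counts per lesion-bearing patient follow
{1: 0.50, 2: 0.30, 3: 0.15, 4: 0.05} (mean 1.75, matching ≈ 420 lesions in
239 lesion-bearing men), sextants per lesion {1: 0.50, 2: 0.35, 3: 0.15}.
Diseased patients carry one sPC index lesion (secondary lesions are sPC with
probability 0.05, and off-lesion sextants harbor systematic-only sPC with
probability 0.08 — the "cancer outside lesions" route); the rare diseased
no-lesion patient is detectable only by systematic cores.  Four targeted
cores per lesion and four systematic cores per sextant (≈ 31 cores/patient,
matching the clinical median) hit sPC-bearing tissue with per-core detection
probabilities 0.80 (targeted) and 0.65 (systematic); the designated disease
state is always confirmed by at least one core, so the intended truth and the
fused truth coincide by construction — and the package cross-checks fusion
output against the generator's intended truth on every generated exam.
Significant cores draw ISUP ∈ {2..5} with probabilities (0.61, 0.17, 0.065,
0.155), the grade mix of the clinical cohort.

Drift: a positive per-batch drift `δ` lowers the category-3 cutpoint of both
classes by δ·batch_index — category-3 reading becomes more liberal, so
PI-RADS ≥ 3 specificity falls over time while the score distribution stays
stationary; this reproduces the qualitative signature the dynamic scheme is
designed to absorb (d3 moving while f3 stands still).  No quantitative drift
magnitude is claimed; it is a mechanism, and tests use δ = 0.05–0.12 per
batch, which produces a clearly visible but non-degenerate shift.

What the generator does **not** emulate: MRI intensities or scanner physics,
realistic prostate geometry (sextant assignments are random subsets, not
contiguous anatomy), registration error between cores and imaging,
inter-reader variability structure beyond a single latent, or correlations
between PSA/referral and disease.  Passing tests therefore demonstrate the
correctness and calibration of the *analysis machinery* under the stated
statistical structure, not clinical performance of any model.

Voxel phantoms for the Dice analysis are sums of clipped Gaussian blobs with
ellipsoidal "manual" VOIs offset by a stated jitter, so every overlap count
is exactly enumerable by brute force.

## Numerical and reproducibility choices

* All randomness flows from one integer seed through
  `numpy.random.default_rng`; the same seed reproduces cohorts bit-identically
  (CSV round-trips use 17-significant-digit formatting and round-trip float
  parsing).
* Default seed 20170101.
* ROC candidate grids make all calibration outputs exact members of the
  observed score set; ties in distance matching resolve deterministically.
* Problem sizes in the shipped tests: 300-exam calibration windows, 312/259
  prior/current deployment streams (the study's shape), 6 000–20 000-patient
  cohorts for marginal-calibration checks, 20 000-replicate bootstrap oracles,
  and ≤ 21³ voxel phantoms.

## Known limitations

* The exact fusion mapping, threshold-matching criterion, and Holm family
  sizes of the original clinical analysis are not published in full; the
  package documents its choices (maximum-evidence fusion, Euclidean working-
  point matching, per-table families) as its own, and they should be treated
  as one reasonable realization, not a reconstruction.
* The relative-PV Wald test is asymptotic; for very sparse paired tables its
  p-values can deviate noticeably from resampling-based answers.
* Clinical threshold values (e.g. f3 = 0.20) and cohort Dice means are
  functions of unreleased clinical scores/images and are out of scope; the
  package reproduces the *structure* of those analyses on synthetic data.
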