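# deploycal

Simulated clinical deployment and quality-assurance monitoring of a
continuous-score prostate-MRI classifier against radiologist PI-RADS
assessment.

## The problem

When a lesion-detection model with a continuous tumor-probability score (e.g.
a U-Net ensemble applied to bi-parametric prostate MRI) is moved into routine
use, its binary decisions must be kept aligned with the clinical reference —
the radiologists' PI-RADS ≥ 3 and ≥ 4 biopsy-decision cutoffs — even as
reading styles drift.  `deploycal` implements the monitoring loop for this
setting, for biostatisticians and imaging scientists who need to evaluate or
stress-test such a deployment before running it on patients:

* **Ground truth by histology fusion.** Clinically significant prostate
  cancer (sPC) is ISUP grade group ≥ 2.  Targeted lesion cores and systematic
  sextant cores are fused into patient-, sextant-, and lesion-level labels
  under a maximum-evidence rule: any significant core makes its sextant (and,
  for targeted cores, every sextant its lesion overlaps) positive.
* **Working-point threshold calibration.** The patient-level ROC of the model
  score is matched to the radiologist's operating points: the chosen threshold
  `t` minimizes the Euclidean distance
  √((sens(t) − sens_ref)² + (spec(t) − spec_ref)²), ties toward higher
  sensitivity.  Three threshold sets are kept: *fixed* (f3/f4, calibrated once
  on the most recent 300 prior-cohort exams), *dynamic* (d3/d4, prospectively
  recalibrated after every batch of 50 exams on a sliding 300-exam look-back
  window mixing `N_p` prior and `N_c` current exams, `N_p + N_c = 300`), and
  *limit* (l3/l4, the hindsight optimum from the full current cohort).
* **Paired diagnostic statistics.** Sensitivity/specificity comparisons use
  the McNemar test (exact binomial for ≤ 25 discordant pairs, continuity-
  corrected χ² above); PPV/NPV comparisons of paired rules use a Wald test on
  log relative predictive value, rPPV = PPV_A/PPV_B, with delta-method
  variance from the paired 2×2×2 multinomial (Moskowitz–Pepe); Holm step-down
  adjustment per table family; Clopper–Pearson 95% CIs.
* **Conjunction ("virtual second reader") analysis.** A unit is positive only
  when radiologist and model agree; paired tables, PPV/NPV, and relative-PV
  tests at patient, sextant, and lesion level.
* **Segmentation overlap.** Lesions are extracted from 3-D probability maps
  as 26-connected components above threshold inside the prostate and scored
  against manual VOIs with the Dice coefficient 2|A∩B|/(|A|+|B|).
* **Synthetic cohorts.** A generator reproduces the statistical structure of
  the clinical setting — 108/259 sPC prevalence, PI-RADS ≥ 3/≥ 4 patient
  operating points at (98 %, 17 %) and (84 %, 58 %), a model score correlated
  with the radiologist latent through a Gaussian copula, multi-lesion sextant
  anatomy, targeted plus systematic cores, and optional linear drift of the
  category-3 cutpoint — so every stage is testable without clinical data.

## Worked example

```python
from deploycal import generate_cohort, default_paper_config, run_deployment

prior, prior_truth = generate_cohort(default_paper_config(n_patients=312, seed=1), id_prefix="PR")
current, current_truth = generate_cohort(
    default_paper_config(n_patients=259, seed=2), start_index=1000, id_prefix="CU")

report, schedule = run_deployment(prior, current, prior_truth, current_truth,
                                  window=300, batch=50)
print(f"fixed  thresholds: t3={report.fixed.t3:.3f}  t4={report.fixed.t4:.3f}")
print(f"limit  thresholds: t3={report.limit.t3:.3f}  t4={report.limit.t4:.3f}")
for step in schedule:
    w = step.window
    print(f"step {step.step}: window N_p={w.n_prior:3d} N_c={w.n_current:3d}  "
          f"d3={step.thresholds.t3:.3f} d4={step.thresholds.t4:.3f}")
```

prints

```
fixed  thresholds: t3=0.121  t4=0.344
limit  thresholds: t3=0.181  t4=0.356
step 0: window N_p=300 N_c=  0  d3=0.121 d4=0.344
step 1: window N_p=250 N_c= 50  d3=0.138 d4=0.340
step 2: window N_p=200 N_c=100  d3=0.161 d4=0.340
step 3: window N_p=150 N_c=150  d3=0.180 d4=0.340
step 4: window N_p=100 N_c=200  d3=0.196 d4=0.359
step 5: window N_p= 41 N_c=259  d3=0.182 d4=0.357
```

Step 0's dynamic thresholds equal the fixed set; each later step is
recalibrated on the most recent 300 examinations (the prior share `N_p`
shrinking from 300 to 41 as current exams accumulate); the five applied
batches have sizes 50, 50, 50, 50, 59 (the remainder is merged into the last
batch), and step 5 is computed after the final exam but applied to nothing.
On this stationary stream the final dynamic thresholds end near the limit
values, as intended.  The report's performance tables carry every percentage
with its counts, e.g. at patient level on this cohort:

```
model >= d3 : sensitivity 98% (107/109), specificity 23% (34/150)
PI-RADS >= 3: sensitivity 99% (108/109), specificity 27% (41/150)
```

The same pipeline is available from the shell:

```bash
deploycal simulate --n 320 --seed 1 --out prior/
deploycal simulate --n 259 --seed 2 --out current/
deploycal deploy --prior prior/ --current current/ --window 300 --batch 50 --out report/
deploycal cooccur --cohort current/ --thresholds thr.json --out tables/
```

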