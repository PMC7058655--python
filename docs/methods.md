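# Methods

## The problem and the model

Community-acquired bloodstream infection (CA-BSI) is diagnosed on the day
a positive blood culture is drawn (day 0, "D0"), but the host response
begins earlier. Given each patient's routine laboratory history in the 30
days before D0, the package asks *when* the mean trajectories of
C-reactive protein (CRP, mg/l, a positive acute-phase protein) and plasma
albumin (PA, g/l, a negative one) change course.

The cohort-level estimator is a **broken-stick regression**: the pooled
per-day mean concentration `y(t)` on days `t = -30 … 1` is modelled as two
straight lines joined at an unknown change-point `c`,

```
y(t) = L + b1 (t - c)     for t <= c
y(t) = L + b2 (t - c)     for t >  c
```

with `L` the level at the change-point and `b1`, `b2` the segment slopes
(units/day). Continuity at `c` is structural: the design matrix columns
are `[1, min(t - c, 0), max(t - c, 0)]`, so the left and right limits
agree exactly for every parameter vector — never a penalty.

### Estimation

For fixed `c` the model is linear, so `c` is estimated by **profiling**:
the normal equations are solved in closed form for every candidate on a
grid (default step 0.1 day over the open interval (−29, 0)), all
candidates in one batched solve, and the global minimiser of the residual
sum of squares wins. A candidate is admissible only with ≥2 fitted days
strictly on each side. Exact SSE ties (which arise when the data are truly
a single straight line) break toward the candidate closest to day 0, i.e.
the latest change. Optionally the minimiser is polished by a bounded
scalar search between its two grid neighbours and kept only if it strictly
lowers the SSE — so a grid point that interpolates the data exactly is
never displaced. The fit target is the unweighted daily-mean series (one
point per day, all specimens pooled); weighting days by their specimen
count is available (`weight_by_count=True`) but not the default, since the
analysis being reproduced fits the observed mean points directly.

The nesting property `SSE(broken stick) ≤ SSE(single OLS line)` holds by
construction (equal slopes are an interior point of the parameter space at
any admissible `c`), and is verified by test.

### Inference

All confidence intervals are **percentile bootstrap over patients**
(default 1000 replications): patients are resampled with replacement, the
pooled daily means rebuilt, and the model refitted per replicate; the CI
is the 2.5th–97.5th percentile of the replicate distribution. The
resampling unit is the patient, not the specimen or the day, respecting
within-patient dependence. Group differences resample each group
independently, with each group's index stream keyed to the group's
identity — hence comparing a group with itself gives exactly zero
differences, and swapping the groups exactly negates every replicate. A
difference is *significant* when its 95% interval excludes zero; no
multiple-testing correction is applied. Replicates whose fit fails are
dropped and counted (`n_failed`); more than 50% failures aborts with a
diagnostic naming the group. Percentile (rather than BCa) intervals are
used because the resampling scheme being mirrored states only "bootstrap,
1000 replications".

### Preprocessing

* Relative days are whole-day calendar differences from the index blood
  culture; the analysis window is `[-30, 1]` inclusive.
* CRP values below the 10 mg/l detection limit are replaced by an
  independent draw from the discrete uniform on {0, …, 9} mg/l (values at
  this scale are reported as integers); a continuous-uniform option
  exists. Albumin has no detection-limit rule and passing albumin to the
  imputer is an error.
* Albumin values strictly below 11 g/l are excluded as implausible.
* Eligibility per biomarker: ≥1 measurement in days [−30, −1] **and** ≥1
  at day 0 or 1, of the same biomarker. Patients measured for only one
  biomarker stay in that biomarker's cohort; the intersection cohort is
  exposed separately.
* Daily means pool every specimen (two same-day specimens from one
  patient both count). Whether the original analysis first averaged
  within patient is not recoverable; pooling matches its specimen-level
  daily counts. Median aggregation is available as an option.

### Per-patient slopes

For patients with ≥2 specimens (on ≥2 distinct days) in both a fixed
early and a fixed late window, OLS slopes are fitted per window from that
patient's specimens alone. Default windows are the whole-day renderings
of the cohort change-points: CRP −30..−4 / −3..1, albumin −30..−2 /
−1..1. The summary proportion counts a strictly positive late slope for
CRP and strictly negative for albumin; "marked" change has no published
numeric threshold, so strict sign is the default and a magnitude
threshold is a config option. Windows whose specimens all fall on one day
leave the slope undefined; such patients are excluded with a reason.

## The synthetic cohort generator

No public data exist (the source registry is not deposited), so every
stage is exercised on synthetic cohorts. The generator emulates:

* **Sampling**: each patient yields a specimen of each biomarker on each
  day with an independent Bernoulli probability from the sampling
  profile. The reference profile is 0.11/day for days −30..−3, then 0.17,
  0.33, 1.0, 0.75 on days −2..1 — the reported daily specimen counts of
  the original CRP cohort divided by its size, capped at 1 (on D0 real
  patients sometimes gave several specimens; the Bernoulli model emits at
  most one per day).
* **Mean structure**: a broken-stick mean per biomarker per microbial
  group. The reference scenario uses the published overall fits for all
  groups — CRP: change-point −3.1 d, slopes −1.5 → 36.3 mg/l/day, level
  70 mg/l; albumin: −1.3 d, 0.1 → −1.8 g/l/day, level 33 g/l. The levels
  are calibrated to the reported concentration ranges (CRP >60 mg/l,
  albumin <35 g/l through most of the window) since only figures show
  them. Published per-group fits ship as `REFERENCE_GROUP_KINETICS`.
* **Noise**: CRP is right-skewed, so it gets multiplicative log-normal
  noise, mean-preserving by construction (`exp(N(-σ²/2, σ))`) so that the
  *arithmetic mean* trajectory — the quantity the estimator targets — is
  exactly the broken stick. Albumin gets additive normal noise. The
  magnitudes are calibration choices, not published values:
  `crp_noise_sd_log = 0.6` (coefficient of variation ≈ 0.66, typical of
  CRP in acute cohorts) and `pa_noise_sd = 3 g/l`. Negative simulated
  concentrations are truncated at 0.
* **Censoring**: CRP below 10 mg/l is emitted flagged `below_lod` with
  the limit as the recorded value; albumin below 11 g/l passes through
  unflagged so the exclusion filter has work to do.
* **Heterogeneity**: an optional additive patient-level random intercept
  (default SD 0) — the base scenario matches a mean-level analysis.
* Microbial group probabilities 0.45/0.48/0.07 (Gram-positive /
  Gram-negative / polymicrobial), typical for Danish CA-BSI; the exact
  split is not recoverable from the available text.

What the generator does **not** emulate: within-day kinetics, mechanistic
acute-phase physiology, informative sampling (sicker patients being
tested more), serial correlation of within-patient noise, and multiple
specimens per patient-day. Passing tests therefore demonstrate that the
estimator and inference machinery are correct under the stated data
structure, not that the clinical findings generalise.

## Reproducibility and numerics

One root seed (`numpy` `SeedSequence`) spawns independent substreams per
stage, so any stage can be rerun in isolation; pipeline reruns with the
same config are byte-identical. Simulation, imputation and every
bootstrap accept either a seed or a `Generator`. Grid candidates are
rounded to 10 decimals to keep floating-point arange drift out of
tie-breaking; the refinement tolerance is `xatol = 1e-10`; singular
candidate systems are skipped rather than regularised.

## Problem sizes used in the checks

The parameter-recovery study simulates 200 cohorts of 500 patients (about
the published cohort's size) and checks that the mean recovered parameter
falls inside the published 95% CI, comparing at the CI's printed
precision. Calibration checks run at reduced settings: 200 bootstrap
replicates, grid-only change-points (no sub-grid refinement), cohorts of
200–300 patients — sizes at which the null rejection rate and CI coverage
are stable to within binomial 3-SE bands.

## Known limitations

* The published albumin pre-change slope (0.1 g/l/day) sits exactly at
  the upper bound of its own printed CI (0.03–0.10), presumably a
  rounding artefact; with the truth on the CI boundary roughly half of
  all unbiased single-cohort estimates must fall outside, so the
  single-cohort in-CI rate for this one parameter cannot reach high
  coverage and the corresponding check documents this honestly.
* The per-patient acute-direction proportions depend strongly on the
  (unpublished) noise magnitudes; the package reports them but asserts no
  published value.
* A change-point on day 0 itself is not estimable from daily data ending
  at day 1: at least two fitted days must follow the change, so the
  search grid ends just below 0.
* Single change-point only; no splines, no mixed-effects per-patient
  curves, no multi-breakpoint models.
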