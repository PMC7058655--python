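# bsikinetics

Kinetics of C-reactive protein (CRP) and plasma albumin (PA) in the 30
days before community-acquired bloodstream infection (CA-BSI), as a
tested, reusable Python library.

Routine laboratory histories show that inflammation markers start moving
*before* the blood culture that diagnoses a BSI is drawn (day 0). This
package estimates when: the pooled per-day mean concentration is modelled
as a **broken stick** — two straight lines joined at an unknown
change-point `c`,

```
y(t) = L + b1 (t − c)   for t ≤ c        y(t) = L + b2 (t − c)   for t > c
```

with `c` profiled over a grid (the linear parameters solve in closed form
at each candidate) and 95% confidence intervals from a patient-level
percentile bootstrap (1000 replications; a difference is significant when
its 95% interval excludes zero). Around the estimator sit the pieces a
real analysis needs: relative-day indexing, imputation of CRP values
below the 10 mg/l detection limit (uniform on 0–9 mg/l), exclusion of
implausible albumin (<11 g/l), per-biomarker eligibility filtering (≥1
measurement in days −30..−1 and ≥1 at day 0/1), bootstrap comparisons of
parameters between microbial groups, per-patient two-window slopes, and a
synthetic-cohort generator that emulates the study's data structure —
irregular sampling that densifies sharply near diagnosis, right-skewed
CRP noise, normal albumin noise, and detection-limit censoring. See
`docs/methods.md` for the model, assumptions and calibration choices.

Intended users: biostatisticians and clinical epidemiologists working
with longitudinal laboratory data around an index event.

## Worked example

Simulate a 500-patient cohort whose true kinetics are the published
overall CRP/albumin fits, then recover them with bootstrap CIs:

```python
import numpy as np
from bsikinetics import (Biomarker, breakpoint_cis, generate_cohort,
                         preprocess_cohort, reference_scenario, select_cohort)

cohort = generate_cohort(reference_scenario(n_patients=500, seed=11))
cohort, _ = preprocess_cohort(cohort, rng=11)
eligible = select_cohort(cohort, Biomarker.CRP)
fit = breakpoint_cis(eligible, Biomarker.CRP, n_reps=500,
                     rng=np.random.default_rng(0))
```

Output (from `examples/02_fit_broken_stick.py`):

```
CRP (500 eligible patients)
  change-point day:  -3.09  (95% CI -3.46 to -2.89)
  slope before:      -1.38 mg/l/day (95% CI -1.81 to -0.94)
  slope after:       36.55 mg/l/day (95% CI 32.41 to 40.00)

PA (493 eligible patients)
  change-point day:  -1.28  (95% CI -1.57 to -1.05)
  slope before:       0.13 g/l/day (95% CI 0.11 to 0.15)
  slope after:       -2.03 g/l/day (95% CI -2.29 to -1.66)
```

Reading: in this simulated cohort CRP drifted slightly downward
(−1.4 mg/l/day) until about 3.1 days before diagnosis, then rose steeply
(+37 mg/l/day); albumin showed the inverse pattern, turning downward
about 1.3 days before diagnosis — each recovering its simulation truth.

The `examples/` directory has one short script per capability
(simulation, fitting, group comparison, individual slopes, full
pipeline). A thin CLI wraps the same calls:

```bash
bsikinetics simulate --seed 3 --n-patients 500 --out cohort.csv
bsikinetics fit --measurements cohort.csv --patients cohort.patients.csv \
    --biomarker CRP --out fit.json
bsikinetics run-all --seed 7 --out results/
```

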