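# pshtraj

Trajectory phenotyping of sympathetic hyperactivity after traumatic brain
injury (TBI), built for neurocritical-care researchers who want to move
beyond a binary paroxysmal-sympathetic-hyperactivity (PSH) diagnosis and
study how autonomic symptom burden *evolves* over the first two weeks of
ICU care.

## What it does

Paroxysmal Sympathetic Hyperactivity is quantified daily with the Clinical
Feature Scale (CFS) of the PSH Assessment Measure: six categories — heart
rate, systolic blood pressure, respiratory rate, temperature, sweating,
posturing — each scored 0–3, totalling 0–18 per day.  `pshtraj` implements
the full analysis pipeline around that instrument:

1. **Scoring** (`pshtraj.scoring`) — converts a raw long-format vital-sign
   stream into daily CFS scores using the *highest* value in each 24-hour
   window after admission, applies the any-mention→2 rule to sweating and
   posturing note flags, drops day 0 (resuscitation/stabilization) and
   assembles 13-day trajectories (days 1–13, linear interpolation of wholly
   missing days).  Also tallies the 11-item Diagnosis Likelihood Tool (DLT).
2. **Trajectory grouping** (`pshtraj.clustering`) — K-means over the
   dynamic-time-warping (DTW) distance

   `DTW(x, y)² = min over monotone endpoint-aligned warping paths of
   Σ (x_i − y_j)²`

   with DBA (DTW Barycenter Averaging) centroids, best-of-`n_init`
   restarts, and the number of groups suggested by the elbow of the
   inertia curve (maximum discrete second difference), with an explicit
   override for clinical judgment.
3. **Outcome associations** (`pshtraj.associations`) — chi-squared tests
   for categorical outcomes (PSH diagnosis, survival), one-way ANOVA for
   continuous ones (DLT, length of stay, ventilator days), per-group odds
   with Wald CIs and means with t CIs.
4. **Admission predictors** (`pshtraj.regression`) — univariate screening
   (ANOVA / chi-squared) followed by multinomial logistic regression with
   forward stepwise selection by likelihood-ratio tests; odds ratios per
   natural unit against a reference group.
5. **Synthetic cohorts** (`pshtraj.simulate`) — a generator with four
   latent trajectory archetypes (persistently low, decreasing, increasing,
   persistently high), group-conditional covariates and outcomes, and an
   exact inverse-scoring property: scoring the generated vitals reproduces
   the generated daily sub-scores bit-for-bit.  Every stage of the pipeline
   is testable without access to protected health data.

## Worked example

A complete run on a 200-patient synthetic cohort (seed 5):

```bash
pshtraj simulate --out cohort --seed 5 --n-patients 200
pshtraj score    --vitals cohort/vitals.csv --flags cohort/flags.csv \
                 --admissions cohort/admissions.csv --out scored
pshtraj cluster  --matrix scored/trajectories.csv --k-range 2..6 --seed 5 --out clustered
pshtraj associate --labels clustered/labels.csv --outcomes cohort/outcomes.csv --out assoc
pshtraj fit      --covariates cohort/covariates.csv --types cohort/covariate_types.csv \
                 --labels clustered/labels.csv --out fitted
```

prints (abridged):

```
scored 200 patients (0 excluded)
elbow suggests K=4 (curve written to elbow.csv; override with --k)
K=4, inertia=3203.39, silhouette=0.574
variable  test        statistic  p_value      significant  group_1 group_2 group_3 group_4
psh_case  chi_square  13.68      3.37e-03     True         6/25    38/61   31/69   28/45
dlt       anova       69.98      8.31e-31     True         2.44    6.44    3.91    7.33
icu_los   anova       2.98       3.28e-02     True         16.87   21.53   17.11   21.86
vent_days anova       5.11       1.99e-03     True         14.14   13.82   10.27   15.40
...
selected features: ['mgcs', 'age']
  group feature  odds_ratio   ci_low  ci_high  p_value
group_2     age    0.950648 0.921150 0.981091 0.001650
group_3     age    0.952880 0.923962 0.982704 0.002143
group_4     age    0.948732 0.917396 0.981139 0.002133
```

Reading this: the elbow lands on four trajectory groups, numbered by
ascending early (days 1–3) severity.  PSH diagnosis, day-14 DLT, ICU length
of stay and ventilation days all differ significantly across groups, while
survival and discharge GCS do not — matching how the outcomes were
generated.  Forward stepwise selection keeps exactly the two covariates
that truly drive group membership in the generator (age and motor GCS);
each additional year of age multiplies the odds of belonging to a
higher-severity trajectory group (versus group 1) by ≈ 0.95.  Because
selection tests run at α = 0.05, an occasional spurious covariate can enter
on some seeds; the selection trace in `fitted/model.json` records every
entry decision.

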