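# Methods

## The instrument and the scoring model

The Clinical Feature Scale (CFS) half of the PSH Assessment Measure scores
six categories per day: four physiologic (heart rate, systolic blood
pressure, respiratory rate, temperature), each mapped to 0–3 by three
cutpoints, and two behavioural (sweating, posturing) scored from clinical
notes.  The shipped cutpoints come from the PSH-AM instrument and are
overridable via a YAML rubric:

| category | 1 point ≥ | 2 points ≥ | 3 points ≥ | unit |
|----------|-----------|------------|------------|------|
| HR       | 100       | 120        | 140        | beats/min |
| SBP      | 140       | 160        | 180        | mmHg |
| RR       | 18        | 24         | 30         | breaths/min |
| TEMP     | 37.0      | 38.0       | 39.0       | °C |

Bands are left-closed (a value equal to a cutpoint earns the higher band).
"Blood pressure" is interpreted as systolic; a different parameter name can
be configured.  Temperatures are expected in °C (convert Fahrenheit at
ingest).

Daily scoring uses the **maximum** value of each parameter within the
24-hour window `[admission + d·24 h, admission + (d+1)·24 h)`; windows are
half-open and anchored to admission time (by default the patient's earliest
observation; an explicit admissions table can override).  Sweating and
posturing score 2 for any note mention, 0 otherwise — note text rarely
grades severity, so the moderate level is imputed for any mention.  A
consequence worth remembering: under this binary note rule the *achievable*
daily total is 16 (4×3 + 2 + 2), although the instrument's nominal range
is 0–18.

Day 0 is excluded as the resuscitation/stabilization period; the analysis
series is days 1–13.  A vital category with no data in an otherwise
documented day scores 0 and is flagged (`missing_categories`) — a
conservative choice, since absence of documentation usually reflects
absence of concern rather than absence of physiology.  A *wholly*
undocumented day is filled by linear interpolation between the nearest
scored days (nearest-value carry at the boundaries) and recorded in
`imputed_days`; patients with fewer than two scored days among days 1–13
are excluded with a logged reason.  How the original analysis handled
zero-documentation days is unknown; interpolation is this package's
choice, made because the clustering stage requires complete length-13
series.

The Diagnosis Likelihood Tool (DLT) is handled only as a tally of 11
supplied indicator booleans; deriving the indicators from raw data (episode
detection, medication review) is out of scope.

## Trajectory grouping

Groups are found by K-means under a dynamic-time-warping distance:

* local cost: squared difference; reported distance: square root of the
  minimal accumulated cost, so inertia is a sum of squared DTW distances;
* step pattern `{(1,0), (0,1), (1,1)}`, both endpoints aligned, no global
  band by default (series are only 13 points long);
* **no z-normalization**: the CFS is an absolute, clinically anchored
  scale, and groups are expected to differ in level as well as shape
  (a `normalize=True` switch exists for sensitivity analyses);
* centroid update: DBA initialized at the within-cluster medoid
  (10 inner iterations by default); assignment ties go to the lowest
  centroid index; an emptied cluster is reseeded with the row farthest
  from its assigned centroid;
* `n_init = 10` restarts from sub-seeds derived deterministically from the
  master seed; the best (lowest-inertia) restart is returned.  Within a
  restart the recorded inertia sequence is non-increasing by construction:
  if a DBA update would raise the assignment objective (possible, since
  the barycenter is an approximation), the update is rolled back and the
  restart stops at the previous state.

DTW is not a metric (triangle inequality can fail); it is used only as a
dissimilarity, never for embedding.  Fitted groups are renumbered by
ascending mean of the centroid's first three days so "group 1 = lowest
early severity" is stable across seeds.  Note this orders by *early*
severity: a high-start/decreasing group outranks a low-start/increasing
one even if it ends lower.

The number of groups is suggested by the elbow of the best-of-restarts
inertia curve — the interior K maximizing the discrete second difference,
ties to the smaller K — and is deliberately only a *suggestion*: the CLI
prints the full curve and accepts `--k`, mirroring the domain practice of
tempering the elbow with clinical judgment.  On default synthetic cohorts
of 200 patients the elbow is genuinely borderline between 3 and 4 (the
decreasing and increasing archetypes are the closest pair under DTW and
merge first); at the reference seed (42) it selects 4, and the
lowest-inertia solution at K=4 recovers the generating labels with
ARI ≥ 0.9.

## Association and regression analyses

Categorical outcomes use Pearson's chi-squared test without continuity
correction (a warning is logged when an expected count is below 5, but the
test still runs).  Continuous outcomes use one-way ANOVA computed from
sums of squares — applied even to skewed variables such as length of stay,
for fidelity with the original analysis; Kruskal–Wallis is available as an
option.  The degenerate all-constant case is defined as F = 0, p = 1.  Raw
p-values are reported with a 0.05 flag and no multiple-testing correction.
Per-group odds use Wald intervals on the log-odds scale with no continuity
correction (a zero cell yields odds without a CI); per-group means use
t-based intervals.

Predictor analysis screens each declared covariate univariately at
α = 0.05, then runs forward stepwise selection in a multinomial logistic
regression (softmax link, reference group's coefficients fixed at zero,
Newton optimization via statsmodels, BFGS fallback with a non-converged
flag when the observed information is singular, e.g. under perfect
separation).  The entry criterion is the likelihood-ratio test — the
original procedure names only "forward stepwise selection", and LRT was
chosen over Wald for stability at moderate n; a multi-level categorical
feature enters as a dummy-coded block against its most frequent level.
Continuous covariates are *not* standardized, so odds ratios are per
natural unit (per year, per GCS point).  Missing covariate values are
handled complete-case per fitted model with logged counts.

With screening and entry both at α = 0.05 over several truly null
candidates, occasional spurious entries are expected (measured ≈ 12% of
default-condition cohorts), and the entry test for a covariate *given* an
informative co-predictor has less power than its marginal test — the exact
two-feature recovery rate on default cohorts is about 75–80%, a structural
property of stepwise selection at these sample sizes rather than an
implementation artifact.

## The synthetic cohort generator

The generator is group-first: a latent archetype label is drawn per
patient, then data are drawn conditional on it (so regression-recovery
tests measure discriminative re-identification of a generative truth, not
a causal story).  Defaults:

* archetype mean curves (13 days): flat 2.0; 8.0→3.0 linear; 3.0→9.0
  linear; flat 10.0 — free constants chosen for qualitative shape and
  mutual separation (pairwise DTW > 5× noise SD); Gaussian noise
  (SD 1.5) is added to the daily *total*, then rounded and clipped to the
  achievable range [0, 16];
* mixing proportions 0.14 / 0.33 / 0.29 / 0.24;
* the daily total is split across categories by a deterministic greedy
  rule (vitals round-robin up to 3 each, then sweating and posturing in
  steps of 2), and raw vital samples (≥3 per category per day) are placed
  so the window maximum falls strictly inside the target band — top band:
  band start plus an exponential tail clipped at physiologic caps
  (HR ≤ 220, SBP ≤ 260, RR ≤ 60, TEMP ≤ 43).  Scoring the generated
  stream reproduces the generated sub-scores exactly, including through a
  CSV round trip;
* covariates: age ~ Normal(52/48/40/38 by group, SD 18) truncated to
  [18, 95] (truncation lifts group means by up to ~1–4 years relative to
  the nominal centers; tests compare against the analytic truncated mean);
  motor GCS ~ rounded clipped Normal on 1–6 with group centers
  (4, 5, 3, 2) and SD 2.5, a dispersion wide enough that group quartiles
  span most of the scale, as admission motor GCS does; BMI, ISS, head
  AIS, sex and
  ICP-monitor placement are group-independent noise covariates;
* outcomes: PSH ~ Bernoulli(0.26/0.38/0.57/0.65 by group); DLT ~
  Binomial(11, q_g) with q = (0.18, 0.36, 0.60, 0.68), increasing in group
  severity; ICU/hospital length of stay and ventilation days are
  group-shifted lognormals (σ = 0.5); survival (p = 0.94) and discharge
  GCS components are group-independent, because no association was
  expected for them.

What the generator does **not** emulate: intra-day paroxysm dynamics or
circadian structure (samples are uniform within the day), informative or
block missingness (only complete days are generated), covariate-first
causal structure, or correlated covariates.  Passing recovery tests on
these cohorts therefore demonstrates the pipeline's machinery is correct
under the stated generative model — not that real EHR data would yield
four groups or these effect sizes.

## Numerical choices and problem sizes

* DTW is exact dynamic programming; one-to-many accumulation is vectorized
  over patients, which keeps cohort-scale K-means in pure numpy.
* Optimizer tolerances: K-means stops on unchanged labels or relative
  inertia change < 1e-6 (50 iteration cap); DBA stops on coordinate change
  < 1e-6 (10 iterations inside K-means); the multinomial Newton fit uses
  statsmodels defaults with gradient tolerance 1e-8.
* Elbow ties break to the smaller K; DTW path backtracking breaks ties
  toward the diagonal; stepwise ties break by larger statistic, then input
  order.  All stochastic operations are reproducible from a single integer
  seed (restart sub-seeds are spawned deterministically).
* Reference problem sizes used in validation: a 200-patient cohort
  (seed 42) for clustering recovery and elbow selection; 221-patient
  cohorts (50 seeds) for stepwise recovery; n = 5000 × 20 seeds for
  multinomial parameter recovery; 1000 null replicates for test sizes;
  all ternary sequence pairs up to length 5 for DTW enumeration; 1000
  random patient-days for the scoring round trip.

## Known limitations

* The interpolation policy for missing days and the equal-weight handling
  of the six CFS categories are design choices, not validated clinical
  conventions.
* ANOVA on skewed length-of-stay variables is retained for fidelity;
  rank-based alternatives typically have better calibration there.
* The elbow statistic on 13-point series with four latent shapes is
  borderline by nature; treat the suggested K as a starting point.
* Stepwise selection inherits the usual caveats (greedy, post-selection
  inference invalid for the reported p-values).
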