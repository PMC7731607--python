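# Methods

## The prediction model

The admission score targets women undergoing a trial of labour after one
previous lower-segment cesarean (singleton, vertex, ≥37 completed weeks,
maternal age 18–35, non-recurrent primary indication). Six covariates
known at admission each score 0/1/2 points and the total (0–12) is
reported in four bins. The model treats the covariates as independent
additive contributions on the point scale; no interactions, no
continuous weighting. A four-variable comparator
(`troyer_parisi_score`) counts risk factors instead, with the opposite
orientation (0 = most favourable).

### Boundary conventions

The published category tables overlap at age 25 and 30, leave BMI
[29, 30) unassigned, and give gestational age as "39–40" completed
weeks. The package closes these deterministically, favouring the
middle category at shared endpoints:

* age: [18, 25) → 2, [25, 30] → 1, (30, 35] → 0
* gestational age: < 39 → 0, [39, 41) → 1, ≥ 41 → 2
* BMI: < 25 → 2, [25, 30) → 1, ≥ 30 → 0
* EFW: < 2500 → 2, [2500, 3500] → 1, > 3500 → 0

These are conventions of this implementation, not statements of the
original authors' intent; all are fields of `ScoreBoundaries` so a
sensitivity analysis over alternative readings is a one-line change.
Johnson's formula constants (offsets 11/12, 155 g/cm) come from
standard obstetric references and sit in `JohnsonParams`. When both a
direct EFW and a fundal-height pair are supplied, the direct
measurement wins; disagreement beyond 10% triggers a warning rather
than silent acceptance. Missing values fail loudly per field — a
clinical score must not impute silently.

Free-text indications map onto the three scored categories only through
an explicit alias table (`INDICATION_ALIASES`); unknown text is an
error listing the categories, never a silent fall-through to the
zero-point group.

## Synthetic cohorts

`generate_cohort` emulates an admission cohort so the evaluation
pipeline can be exercised, and its estimators checked, without patient
data. Covariates are sampled independently from marginal distributions
(`CovariateParams`):

| covariate | default | anchored to data? |
|---|---|---|
| age | TruncNormal(25.84, 4.20) on [18, 35] | yes — published cohort mean ± SD |
| gestational age | TruncNormal(40.0, 1.7) on [37, 42] wk | invented |
| BMI | TruncNormal(26, 5) on [16, 45] kg/m² | invented |
| EFW | TruncNormal(2950, 500) on [1500, 4500] g | invented |
| indication | 0.50 / 0.10 / 0.40 over the three categories | invented |
| Bishop | categorical on 0–10; mass 0.30/0.10/0.60 on 0–3/4–5/6–10 | invented |
| parity, labour onset, interval, history flags | see `CovariateParams` | invented |

The invented marginals were fixed once, by convolving the six induced
component-point distributions (`induced_score_pmf`, an exact closed
form under independence) and choosing parameters whose induced bin
frequencies approximate the development cohort's 7.30/40.10/47.3/5.30%
split; the defaults achieve ≈5.2/42.3/46.7/5.9%. They are config
values, not logic. Real cohorts differ in ways the generator does not
model: covariates are correlated (a Gaussian-copula extension is a
natural follow-up; the published study reports only marginals), scores
within a bin need not be uniform, and site case-mix varies. Passing
tests therefore demonstrate correctness of the machinery and internal
consistency of the published summaries — not external validity of the
score.

Outcomes come from one of two models. Under `BIN_CALIBRATED` each
patient succeeds with her bin's configured probability (defaults
34/68/90/97%); the implied overall rate, Σ f_b·p_b ≈ 0.775, matches the
published 78%. Under `LOGISTIC`, log-odds are b₀ + Σ log(OR_i)·x_i
with covariates on their natural scales (per week, per Bishop point,
per kg/m², flags 0/1 — matching the "per 1 unit increase" reading of
the published adjusted ORs) and defaults 2.047 / 3.082 / 0.832 / 2.58 /
5.138. The intercept is calibrated by bisection on a 50,000-draw
covariate sample until the mean success probability is within 1e-3 of
the target rate (default 0.78); the mean is strictly increasing in b₀,
so bisection over [−200, 200] cannot stall. One RNG stream per cohort,
seeded from config, makes a cohort a pure function of its
configuration; bootstrap seeds are supplied separately downstream.

Because the logistic generator uses auxiliary covariates (parity,
spontaneous labour) alongside the model's six, parameter-recovery fits
use a design that nests the generator: logistic odds ratios are not
collapsible, so refitting a strict sub-model of the generator would be
attenuated even at infinite n. The six-covariate table inside
`validate` mirrors the published adjusted-OR table and is kept separate
from that recovery design.

## Statistical kernel

* **Logistic regression** — maximum likelihood by IRLS/Newton with
  step-halving (the log-likelihood never decreases), convergence at
  score max-norm < 1e-8, cap 100 iterations. Wald SEs from the inverse
  observed information; Wald (not profile) CIs, matching standard
  "enter method" output. Perfect separation by a single covariate is
  detected before fitting and reported by name; joint separation
  surfaces as divergence (|β| > 25 at the cap). Constant columns are
  rejected as collinear with the intercept.
* **ROC/AUC** — Mann–Whitney convention via midranks (ties count ½),
  oriented so a higher score predicts success; the curve enumerates all
  distinct thresholds and its trapezoidal integral equals the pairwise
  statistic identically (property-tested). AUC on the integer score
  equals AUC on fitted probabilities of any univariate monotone model
  of it, so the choice is immaterial here.
* **AUC interval** — stratified percentile bootstrap (cases resampled
  within outcome class, so every resample keeps both classes), default
  B = 2000, seeded. Percentile rather than DeLong: one shipped method,
  honest at n = 150, trivially deterministic.
* **Two-sample t** — operates on summary statistics so published
  mean±SD tables are directly checkable; pooled-variance Student by
  default (it reproduces the published upper CI bound 2.67 for the
  score comparison between outcome groups), Welch by flag. The
  published lower bound (1.28) is not exactly recovered from the
  rounded summaries — the pooled computation gives 1.286 → 1.29,
  presumably because the original analysis used unrounded data.
* **Chi-square** — Pearson Σ(O−E)²/E without continuity correction by
  default (conventional at these cell sizes); Yates by flag, 2×2 only.

## Validation report

`validate` computes, from one cohort snapshot: the overall success
rate; the four-bin calibration table (observed success per bin next to
the mean fitted probability of the *univariate* score-only logistic —
the score-only and multivariate analyses are deliberately separate);
univariate, six-covariate and auxiliary logistic tables; ROC/AUC with
bootstrap CI; group comparisons (pooled t on continuous covariates, χ²
on indication); and, when a `repeat_indication` column exists, the
tabulation of repeat-cesarean indications among failures. Empty bins
are emitted with explicit nulls (possible at n = 150), never collapsed,
so report shape is stable. All four bins, frequencies to two decimals
and probabilities to whole percent in the TSV rendering; full precision
in JSON. Sections whose inputs are absent are reported absent, never
fabricated. Reports are deterministic given (cohort, seed, B, α);
`replicate` bundles simulate → score → validate and is byte-identical
across runs.

## Problem sizes and numerical choices

Distributional checks in the test suite run at n = 5,000–100,000:
100,000 gives Monte-Carlo standard errors of ~0.1–0.5 percentage points
on bin success rates and Wald SEs small enough that a 3-SE recovery
band is a sharp test, while the whole suite stays fast. The
discrimination simulation in `scripts/acceptance.py` uses n = 200,000
draws from the published bin frequencies; its exact (infinite-n) AUC
under those inputs is 0.7330, comfortably inside the published 95%
interval [0.68, 0.85]. Bisections and IRLS tolerances are stated
above; ties in the AUC are handled by midranks, and `np.quantile`'s
linear interpolation defines the bootstrap percentiles.

## Known limitations

* Independent covariates under-disperse joint risk profiles relative to
  real admissions; treat simulated CIs as machinery checks, not
  clinical estimates.
* The score's external validity, and behaviour outside the inclusion
  window (age, gestational age), are out of scope by design — records
  violating the criteria are rejected, not extrapolated.
* The auxiliary-covariate regression requires all five columns
  complete; partial auxiliary data currently yields an absent section
  rather than a reduced model.
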