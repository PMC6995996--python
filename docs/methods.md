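# Methods

This note documents the models, conventions and design choices behind
`ewscompare`, in the spirit of a statistical software methods appendix. It
states no empirical result that the test suite or `scripts/acceptance.py`
does not itself compute.

## Scoring

NEWS and NEWS2 are deterministic functions of a seven-item observation set.
The weight bands are shipped as CSV configuration
(`src/ewscompare/data/news.csv`, `news2.csv`) mirroring the Royal College of
Physicians charts:

| item | bands (weight) |
|---|---|
| respiratory rate | ≤8 (3), 9–11 (1), 12–20 (0), 21–24 (2), ≥25 (3) |
| temperature (°C) | ≤35.0 (3), 35.1–36.0 (1), 36.1–38.0 (0), 38.1–39.0 (1), ≥39.1 (2) |
| systolic BP | ≤90 (3), 91–100 (2), 101–110 (1), 111–219 (0), ≥220 (3) |
| heart rate | ≤40 (3), 41–50 (1), 51–90 (0), 91–110 (1), 111–130 (2), ≥131 (3) |
| SpO₂ scale 1 | ≤91 (3), 92–93 (2), 94–95 (1), ≥96 (0) |
| SpO₂ scale 2 | ≤83 (3), 84–85 (2), 86–87 (1), 88–92 (0); on O₂: 93–94 (1), 95–96 (2), ≥97 (3); on air ≥93 (0) |
| supplemental O₂ | flat 2 |
| consciousness | A (0), V/P/U (3) |

Conventions, all of which are deliberate decisions where chart semantics
leave room:

- **Boundary handling.** All printed bounds are inclusive. Comparisons
  happen in integer recording units (temperature 0.1 °C, everything else
  1 unit); real-valued inputs are rounded half-up to recording precision
  first, with a 10⁻⁶ guard against binary-float midpoints (38.05 → 38.1).
- **Out-of-range values** (e.g. RR 200) clamp to the nearest extreme band
  rather than erroring: charts are open-ended at the extremes.
- **GCS→AVPU**: 15→A, 9–14→V, 4–8→P, 3→U. Several conversions circulate in
  clinical practice; this common one is fixed here and is configurable.
  It is total over 3–15 and monotone.
- **Complete-case rule.** An observation missing any of the seven inputs
  (including the inspired-gas flag, which the SpO₂ item needs) is
  unscorable and rejected.
- **"On oxygen"** means the inspired-gas flag recorded with the SpO₂
  measurement, never an inference from prescription data.
- The NEWS2 "new confusion" (ACVPU) item is not modelled; consequently
  NEWS2 with scale 1 is identical to NEWS under the shipped tables, which
  the tests assert over a dense grid.

## Cohort and risk groups

Exclusions are applied in a fixed, tallied order: age < 16 → no complete
observation set → discharged alive on the calendar day of admission → no
vital signs in the 24 h before discharge (a proxy for end-of-life
pathways). The order matters only for the stage counts, not for the final
cohort, which the order-invariance test checks.

Risk-group classification is prefix-based on dot-stripped ICD-10 codes:
3-character categories for ranged rules (J40–J44, J47, E84, E66, G12, G70,
G71, J96) and 4 significant characters for G47.3 / M95.4 / Q67.8. The
neuromuscular and chest-wall codes qualify only together with a J96 code.
"Documented T2RF" is carried as a boolean oxygen-prescription flag, since
the source form is site-specific. Documented and at-risk groups may
overlap; "not at risk" is their complement, so the three reported groups
cover the cohort.

## Outcomes

Each endpoint is evaluated on the half-open window
`(observed_at, observed_at + 24 h]`: an event at the observation instant
does not count, an event exactly 24 h later does. When an admission ends in
death without an explicit death time, the discharge instant is the death
time. Observations after a first unanticipated ICU admission are retained
by default (a censoring switch exists for sensitivity analysis).
Observation sets are analysed as independent rows, matching the standard
design of aggregate-score validation studies; the bootstrap can optionally
resample whole admissions instead.

The NEWS2 column's SpO₂ scale follows a policy: `always` (default; scale 2
everywhere, which in the not-at-risk group measures the cost of using the
scale in error), `by_group` (scale 2 only for documented/at-risk — the
intended use), or `never` (scale 1, making NEWS2 ≡ NEWS here).

## Discrimination

The c-statistic is computed by the rank (Mann–Whitney) identity with tie
correction, which equals the trapezoidal area under the ROC curve; both
paths exist and their agreement is asserted. Triggering is `score ≥
threshold`. System comparison uses a paired bootstrap: each of 2000
replicates resamples observation rows with replacement and evaluates both
systems on the same resample; 95% percentile intervals are reported for
each AUROC and for the difference, with significance defined as the
difference CI excluding zero and a companion two-sided bootstrap p-value
`2·min(P(Δ≤0), P(Δ≥0))`. Replicates that resample a single outcome class
are redrawn (counted, capped). Strata with fewer than 100 outcome events
are flagged as unreliable. Calibration is not assessed: aggregate scores
are not probability estimates. Efficiency curves report, per integer
threshold, the fraction of all observations triggering (workload) and the
fraction of outcome-positive observations triggering (sensitivity).

## Missing data

Multiple imputation uses chained equations with predictive-mean matching:
each incomplete variable is regressed by OLS on the other six over the
current completed data; each missing cell takes the observed value of one
of the 5 nearest donors by predicted mean (drawn uniformly); 10 sweeps,
m = 5 datasets, all configurable. PMM keeps categorical inputs
(AVPU ordinal, inspired gas) in their valid label sets and continuous
inputs inside the observed range, and observed cells are never altered.
Scores are recomputed on each completed dataset — never imputed directly,
because they are deterministic functions of the vitals. Per-dataset AUROCs
are pooled by Rubin's rules on the logit scale: within-imputation variance
from a 200-replicate row bootstrap, between-imputation variance across
datasets, Barnard–Rubin degrees of freedom, back-transformed interval.
Only MCAR missingness is modelled; informative missingness is out of scope.

## Synthetic cohorts

The generator emulates the structure of a multi-hospital vital-signs
database (which cannot be shared in real form): five hospitals in two
groups, with oxygen-prescription (documented-T2RF) data only at the
four-hospital group, emulating a site-specific form.

- **Severity process.** Each admission carries a latent severity: a
  standard-normal AR(1) on a 4-hourly grid (ρ = 0.85 per step) plus a
  persistent frailty offset (sd 0.7, +0.3 for documented-T2RF admissions).
  This is the simplest process that yields realistic within-admission score
  autocorrelation while keeping analytic control.
- **Vitals** are monotone transforms of current severity plus Gaussian
  noise, rounded to recording precision (e.g. RR = 17 + 3.2·s). One
  coupling multiplier scales every channel's severity response, giving a
  monotone handle on achievable discrimination. About 10% of observations
  report GCS instead of AVPU to exercise the conversion.
- **SpO₂ by group.** Documented-T2RF admissions draw a bell-shaped
  saturation setpoint (mean 91.5, sd 3); at-risk admissions N(94.5, 2.5);
  not-at-risk admissions a right-skewed setpoint concentrated in 96–100
  (100 − 2 − Exp(1.3)). Supplemental-oxygen probability is group-dependent
  (0.45 / 0.20 / 0.08 at baseline) and increases with severity.
- **Events.** Death, unanticipated ICU admission and cardiac arrest fire
  from a per-interval complementary-log-log hazard linear in current
  severity (slope 1.5). The intercept is calibrated per risk group by
  bisection against the realised admission-level rate on the drawn
  severity paths, so configured marginal rates are hit to within one
  admission; infeasible targets raise an error reporting the achievable
  range. Default rates follow the published group marginals: mortality
  11.4% / 4.5% / 2.3%, ICU 3.2% / 1.2% / 0.8%, arrest 1.3% / 0.6% / 0.3%
  (documented / at-risk / not-at-risk). Group shares default to the
  published cohort (0.55% documented, 19.5% at risk, 80.3% of documented
  also at risk).
- **Length of stay** is log-normal with group medians 6.7 / 4.0 / 2.8 days,
  truncated at death. Small fractions of under-16 admissions (1%) and of
  admissions whose observations stop >24 h before discharge (1%) exercise
  the exclusion flowchart; same-day live discharges arise naturally from
  the stay distribution.

What passing tests on these cohorts show — and what they do not: the
pipeline recovers known ground truth (configured rates, analytic AUROCs,
monotone coupling–discrimination trends) under a correctly specified,
stationary generative model with MCAR missingness. Real observation data
have measurement artefacts, treatment feedback, ward transfers,
non-stationary observation policies and informative missingness, none of
which are modelled; agreement here validates the *code*, not any clinical
claim about the scores.

## Problem sizes and defaults

Desk-scale defaults keep a full run reproducible on a single CPU: the
default study simulates 800 admissions (≈ 24,000 observation sets) with
3% MCAR missingness at the prescription-capable hospitals and 2000
bootstrap replicates. The demonstration study enriches the documented-T2RF
share to 5% — at the population share of 0.55% a few hundred admissions
would leave that stratum nearly empty — while leaving all event rates and
SpO₂ shapes at their population defaults. Calibration checks run at
20,000 admissions; the imputation consistency check at 50,000 observation
rows; bootstrap coverage at 500 simulations × 500 replicates. All
randomness flows from one master seed through named child seeds
(`numpy.random.SeedSequence`), and report bundles contain no wall-clock
timestamps, so identical configuration and seed reproduce outputs byte for
byte.

## Known limitations

- The GCS→AVPU mapping and the exact chart band edges are configuration;
  sites using different conventions must edit the CSVs rather than the code.
- The "new confusion" item of NEWS2 is not modelled, so NEWS2 differences
  here isolate the SpO₂-scale change.
- The cluster (per-admission) bootstrap truncates or cycles resampled
  clusters to a fixed row count to stay rectangular; it is a sensitivity
  option, not the primary method.
- PMM with few donors can underestimate imputation variance when
  missingness is heavy; m and the donor count are configurable.
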