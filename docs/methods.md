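# Methods

## Scope and model

`postaki` re-implements, as a reusable pipeline, the external validation and
clinical-utility assessment of two published logistic prediction models for
outcomes after hospitalization with acute kidney injury (AKI):

- a **90-day death-or-readmission model** for all hospital survivors
  (risk threshold 30% proposed for targeting post-discharge review), and
- a **1-year CKD G4-G5 progression model** for AKI survivors with baseline
  eGFR > 45 mL/min/1.73 m² (thresholds 1% and 10% proposed for nephrology
  follow-up decisions).

Both models are stored as data (`src/postaki/models/*.yaml`): an intercept
plus coded terms, with coefficients equal to the natural log of the
published odds ratios at printed precision. Unrounded derivation
coefficients are not recoverable from the publications and no attempt is
made to reconstruct them. Continuous predictors are not centered. Two
published oddities are kept verbatim and only flagged in the spec files:
the readmissions model's age odds ratio (1.17 "per year older", implausibly
large for a one-year unit) and a residential-care point estimate below its
own confidence bound. The CKD model's discharge-creatinine reference
category is printed "<0.1 mg/dL" in the source; it is treated as a typo for
"<1.0 mg/dL", consistent with the published cohort characteristics.

## Predictor and outcome derivation

**AKI detection** (`preprocessing`) implements two serum-creatinine
algorithm variants. The Grampian variant tests every in-admission
creatinine as an index value against three criteria: (1) a rise > 0.3 mg/dL
above the lowest value of the preceding 48 h; (2) a ≥ 50% rise above the
lowest value of the past 7 days; (3) a ≥ 50% rise above the *median* of
days 8–90 back, falling back to days 91–365 only when no sample exists in
the closer window. The Alberta variant compares the peak in-hospital
creatinine with the most recent *outpatient* baseline 7–365 days before
admission; absence of a qualifying baseline yields an explicit
indeterminate result (`None`), distinct from "no AKI". Staging uses the
KDIGO convention relative to the firing criterion's reference value —
stage 2 at ≥ 2.0×, stage 3 at ≥ 3.0× or an absolute creatinine
≥ 4.0 mg/dL — with the multipliers configurable (`StagingRules`) because
the source publications state only "KDIGO-based". When several criteria
fire, the one giving the highest stage wins; ties break in the order
listed. Urine-output and dialysis criteria are out of scope.

**eGFR** uses the CKD-EPI 2009 equation. The race coefficient is
configurable and off by default, reflecting UK laboratory practice of the
study era (non-Black coefficient applied universally).

**Outcomes.** Windows are half-open at the start and closed at the end,
`(t0, t0 + horizon]`; a death at exactly day 90 counts, at day 91 does not.
CKD G4-G5 requires two outpatient eGFR values < 30 separated by ≥ 90 days
("3 months") within one year of cohort entry; missing data yields `False`,
never an error. The 90-day and 3-month conventions are parameters because
the sources do not state the exact day counts.

## Validation metrics

The C statistic is the Mann-Whitney concordance probability (ties count
half); its interval is a seeded percentile bootstrap, 2,000 resamples by
default — the sources do not state their interval method, so this is a
documented package default, not a claim of fidelity. Calibration slope is
the coefficient of the prognostic index (PI) in a logistic fit of outcome
on PI; the calibration intercept fixes the slope at 1 by entering PI as an
offset. The verbal definition of calibration-in-the-large as a difference
of mean risks conflicts with published values that are clearly on the
log-odds scale; the log-odds offset definition is primary here, and the
risk-difference version is exposed separately as
`calibration_in_the_large_risk_difference`. Risks are clipped to
`[1e-12, 1-1e-12]` before any logit. Decile tables rank by risk with a
stable sort; remainders go to the lowest-risk groups so group sizes always
sum to n.

## Model updating

Recalibration fits `outcome ~ a + b·PI`, then multiplies every coefficient
by `b` and maps the intercept to `a + b·β0`; the recalibrated model is
perfectly calibrated on the fitting cohort by construction, and its
discrimination equals the original's exactly (monotone transform). Refitting
maximizes the likelihood over exactly the original term structure — same
codings, scale divisors, polynomial terms — with no added variables. Fits
are Newton-Raphson (statsmodels), tolerance 1e-8, at most 100 iterations,
failing loudly with iteration diagnostics on non-convergence or separation.
No shrinkage is applied; for small cohorts this is a known limitation.
Updated models carry provenance metadata (method, cohort hash, fit
diagnostics) through the same YAML schema.

## Decision curve analysis

Net benefit at threshold probability p_t is
`TP/n − (FP/n)·p_t/(1−p_t)`; the exchange rate `(1−p_t)/p_t` gives the
acceptable false positives per true positive (9 at p_t = 0.1). Model
strategies treat at predicted risk ≥ threshold (boundary inclusive);
rule strategies are treat-all, treat-none, any AKI, AKI stage 2–3, and
discharge eGFR < 30 (a pragmatic proxy for non-recovery). The default grid
is 0.01–0.50 by 0.01, covering the prespecified 1%, 10% and 30% points; the
source figures do not state their axis range, so the grid is a documented
choice. Curves are not smoothed.

## Process mining

Event logs hold one case per discharged patient: a discharge, optional
monitoring contacts (GP, outpatient clinic, A&E), and one terminal event
(readmission, death, or end of follow-up). Truncation to a 30- or 90-day
horizon drops later events and closes open cases with `end_follow_up`
exactly at the boundary. The directly-follows map counts each consecutive
pair once per occurrence and annotates edges with median transition times
in days (midpoint convention for even counts); node weights are visit
counts, so outgoing edges of every non-terminal activity sum exactly to its
visits. Same-day ties are ordered discharge → monitoring → terminal. An
"unmonitored poor outcome" is a readmission or death with no intervening
care contact; whether A&E counts as a contact is a flag
(`ae_is_monitoring`, default true) because the source narrative is
ambiguous on this point. Top-k edge filtering is provided for display only,
with no claimed fidelity to any commercial tool's path-filtering
heuristics.

## Synthetic cohorts

The real cohorts are not public, so the package ships generators whose
defaults encode the published study conditions:

- **Grampian-like scenario** (default n = 26,575): covariate marginals from
  the published all-survivors table (age 60.9 ± 19.8 y, 12.5% AKI split
  8.7/2.3/1.5% across stages, 71.3% emergency admissions, baseline eGFR
  86.3 ± 26.4, ...), outcome prevalence 2,927/26,575 = 11.0%.
- **Alberta-like scenario** (default n = 9,382): AKI survivors with the
  published marginals and a 1-year CKD G4-G5 prevalence of 140/9,382 =
  1.49%; its data-generating model is the published CKD model itself, whose
  printed coefficients are internally consistent with that prevalence.

Covariates are drawn independently of one another — only marginal
distributions are published. Outcomes follow
`invlogit(shift + slope·PI_true)`, so derivation-to-validation drift
(systematic overprediction, slope damping) can be injected and then
recovered by the updating module; `shift_for_target_mean` solves the shift
for any target mean risk by bisection.

The Grampian scenario's data-generating model keeps the published term
structure with two deliberate departures. First, age is coded per decade:
the printed per-year odds ratio implies prognostic-index spreads of ~10
log-odds and degenerate all-or-nothing risks. Second, the AKI-stage
coefficients are set to odds ratios 7.5/10/12 so that the *marginal* event
rates among AKI survivors land near one in three (≈ 0.33/0.41/0.42 by
stage) — the 90-day readmission burden reported for AKI survivors. With
independent covariates the published *conditional* odds ratios cannot
reproduce those marginal rates, because in real data AKI co-occurs with
age, emergency admission and comorbidity. Each scenario's intercept is
calibrated once to the published prevalence by bisection on a fixed
internal reference draw (seed 20210701), making scenario construction
deterministic. Discharge eGFR is derived from baseline eGFR minus an
AKI-stage-graded decrement (0/10/25/40 units, SD 8) in the Grampian
scenario, and from a creatinine drawn within the discharge category band
converted through CKD-EPI in the Alberta scenario.

The creatinine-series generator builds each AKI case to satisfy exactly one
detection criterion at exactly one stage (multipliers 1.6/2.3/3.4 against
the criterion's reference; 48-hour delta cases are always stage 1, since a
larger rise would also trip the ratio rules), so
generator-vs-detector confusion matrices are exactly diagonal. The pathway
generator gives each poor-outcome case a terminal event at
`1 + Exp(18 days)` capped at the horizon (median ≈ 13 days) and at least
one prior monitoring contact with probability `monitoring_prob_poor`
(default 0.61, i.e. 39% unmonitored, matching the reported 90-day figure);
other cases accrue Poisson(2) contacts and exit at the horizon.

**What passing tests do and do not show.** The generators reproduce
marginal structure, prevalences, miscalibration and monitoring rates — not
joint covariate distributions, informative missingness, record-linkage
error, or seasonal admission patterns. Analytic identities (refit
calibration = (0, 1), P:O = 1, flow conservation, oracle equivalences) hold
regardless of generator realism; the qualitative decision-curve ordering
(model-guided ≥ any-AKI ≥ severe-AKI near the 30% threshold) does depend on
the scenario's stage-graded event rates and is asserted with the
*recalibrated* model as the model-guided strategy — the raw twofold
overpredicting model treats everyone above ~15% true risk at a nominal 30%
threshold and has negative net benefit there, which is itself an instructive
property of miscalibrated model-guided decisions.

## Problem sizes and numerical defaults

Tests run the scenarios at n = 2,000–50,000 (shared fixtures at 8,000–
9,382); the acceptance script uses n = 25,000 for validation and decision
curves, n = 50,000 for drift recovery, and 10,000 cases for pathway mining,
with 200 bootstrap resamples for the reported AUC interval. Bisection
tolerances are 1e-10 on mean risk; logistic fits converge at 1e-8. All
randomness flows from explicit integer seeds through
`numpy.random.default_rng`.

## Known limitations

- Shipped coefficients inherit the printed rounding of the source odds
  ratios; absolute risks from the original models should be audited against
  that precision.
- Confidence intervals are provided only for the C statistic (bootstrap);
  interval methodology for other metrics is out of scope.
- No urine-output AKI criteria, pediatric eGFR equations, survival-time
  discrimination, net reclassification, or monetary cost-effectiveness.
- Original-model derivation (variable selection, bootstrapped shrinkage) is
  deliberately not reproduced.
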