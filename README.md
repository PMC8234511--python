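# postaki

Validation, updating and decision-curve evaluation of risk prediction
models for outcomes after acute kidney injury (AKI), with synthetic
cohorts so the whole pipeline runs without access to any patient data.

Hospital survivors who developed AKI face high risks of early death,
unplanned readmission, and progression to advanced chronic kidney disease
(CKD G4-G5, eGFR < 30 mL/min/1.73 m²), but it is unclear who should be
prioritized for follow-up. Two published logistic models address this: a
90-day death-or-readmission model for all hospital survivors, and a 1-year
CKD G4-G5 progression model for AKI survivors with preserved baseline
kidney function. `postaki` packages those models as data and provides the
full analysis around them, for clinical epidemiologists and prediction-model
researchers:

- **preprocessing** — KDIGO-based AKI detection and staging from serial
  creatinine (two algorithm variants), CKD-EPI (2009) eGFR, and outcome
  ascertainment with explicit window conventions;
- **registry** — the four published coefficient sets
  (`aberdeen_original/refit`, `alberta_original/refit`) as YAML specs,
  scored via the prognostic index `PI = β₀ + Σ βⱼ xⱼ` and risk
  `p = 1/(1+e^{-PI})`;
- **metrics** — C statistic (with seeded bootstrap interval), Brier score,
  predicted-to-observed ratio, calibration intercept/slope on the log-odds
  scale, decile calibration tables and plots;
- **updating** — logistic recalibration through the prognostic index
  (`outcome ~ a + b·PI`, coefficients rescaled by `b`, intercept shifted by
  `a`) and de-novo refitting of the exact original term structure;
- **decision** — decision curve analysis: net benefit
  `TP/n − (FP/n)·p_t/(1−p_t)` per strategy over a threshold grid, 2×2
  classification tables at the prespecified 1%, 10% and 30% thresholds;
- **mining** — directly-follows process maps of post-discharge care event
  logs (case-weighted edges, median transition times) and
  unmonitored-poor-outcome statistics at 30- and 90-day horizons;
- **synthetic** — scenario generators reproducing the published cohort
  marginals, outcome prevalences, configurable miscalibration, and care
  pathways.

## Worked example

Simulate an external validation cohort at the published scale (here
n = 25,000, event prevalence 11%), score it with a model that overpredicts
twofold, then recalibrate and compare follow-up strategies by net benefit:

```python
import postaki as pk
from postaki.synthetic import shift_for_target_mean

config = pk.grampian_scenario(n=25_000, seed=1)
cohort = pk.simulate_cohort(config)
outcome = config.true_model.outcome_label

# emulate an overpredicting external model (P:O ~ 2)
pi = config.true_model.linear_predictor(cohort)
shift = shift_for_target_mean(pi, 2.042 * cohort[outcome].mean())
external = config.true_model.rescaled(shift, 1.0, name="external_original")

report = pk.validate(pk.predicted_risk(external, cohort), cohort[outcome],
                     n_boot=200, seed=1)
print(report.summary())

recal = pk.logistic_recalibration(external, cohort)
for strat in [pk.DecisionStrategy.from_model(recal, "model_guided"),
              pk.DecisionStrategy.from_rule("any_aki"),
              pk.DecisionStrategy.from_rule("aki_stage_2_or_3"),
              pk.DecisionStrategy.from_rule("treat_none")]:
    nb = pk.net_benefit(strat, cohort, 0.30, outcome)
    print(f"net benefit @0.30  {strat.label:<18s} {nb:+.4f}")
```

which prints:

```
Validation of external_original (n=25000, events=2673)
  c_statistic              0.785
  brier                    0.098
  predicted_to_observed    2.042
  calibration_intercept    -1.025
  calibration_slope        0.999
net benefit @0.30  model_guided       +0.0170
net benefit @0.30  any_aki            +0.0077
net benefit @0.30  aki_stage_2_or_3   +0.0051
net benefit @0.30  treat_none         +0.0000
```

Read: the model ranks patients well (C = 0.785) but predicts 2.042 times
too many events (negative calibration intercept −1.025), so its absolute
risks need recalibration before use. At a 30% threshold — where one true
positive is worth `(1−0.3)/0.3 ≈ 2.3` false positives — targeting
follow-up by the recalibrated model yields more net benefit than following
up everyone with AKI, which in turn beats restricting follow-up to severe
(stage 2–3) AKI; doing nothing is the zero line.

A thin CLI wraps the same functions:

```bash
postaki simulate cohort.csv --scenario grampian --n 5000 --seed 1
postaki dca cohort.csv curve.csv --rule treat_all --rule treat_none \
        --rule any_aki --outcome death_or_readmission_90d --report-threshold 0.3
postaki mine events.csv edges.csv --horizon 90
```

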