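# Aberdeen 90-day death-or-readmission model, original derivation
# coefficient set (all hospital survivors).  Odds ratios as published;
# coefficients are taken as ln(odds ratio) at printed precision.
# Known quirks kept verbatim: the age odds ratio is printed "per year
# older" (implausibly large for a 1-year unit) and the residential-care
# point estimate lies below its printed confidence interval.
name: aberdeen_original
outcome: death_or_readmission_90d
intercept: -1.876
terms:
  - predictor: age
    kind: continuous
    scale: 1
    degree: 1
    odds_ratio: 1.17
  - predictor: residential_care
    kind: binary
    odds_ratio: 1.37
  - predictor: rural
    kind: binary
    odds_ratio: 0.86
  - predictor: prior_admissions
    kind: count
    odds_ratio: 1.23
  - predictor: emergency
    kind: binary
    odds_ratio: 1.89
  - predictor: aki_stage
    kind: categorical
    reference: "0"
    odds_ratios:
      "1": 1.50
      "2": 2.23
      "3": 2.80
  # Baseline eGFR modelled per 10 mL/min/1.73 m2 with linear + quadratic terms.
  - predictor: baseline_egfr
    kind: continuous
    scale: 10
    degree: 1
    odds_ratio: 0.87
  - predictor: baseline_egfr
    kind: continuous
    scale: 10
    degree: 2
    odds_ratio: 1.01
  - predictor: cancer
    kind: binary
    odds_ratio: 1.59
  - predictor: cardiac_failure
    kind: binary
    odds_ratio: 1.42
  - predictor: diabetes
    kind: binary
    odds_ratio: 1.38
  - predictor: pulmonary
    kind: binary
    odds_ratio: 1.47
metadata:
  setting: "Grampian 2003 derivation cohort"
  risk_threshold: 0.30
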