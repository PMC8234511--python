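# Aberdeen 90-day death-or-readmission model, published refitted
# validation coefficient set (Grampian 2012).  Same term structure and
# codings as the original model.
name: aberdeen_refit
outcome: death_or_readmission_90d
intercept: -2.196
terms:
  - predictor: age
    kind: continuous
    scale: 1
    degree: 1
    odds_ratio: 1.29
  - predictor: residential_care
    kind: binary
    odds_ratio: 2.46
  - predictor: rural
    kind: binary
    odds_ratio: 0.95
  - predictor: prior_admissions
    kind: count
    odds_ratio: 1.26
  - predictor: emergency
    kind: binary
    odds_ratio: 2.2
  - predictor: aki_stage
    kind: categorical
    reference: "0"
    odds_ratios:
      "1": 3.43
      "2": 5.63
      "3": 5.04
  - predictor: baseline_egfr
    kind: continuous
    scale: 10
    degree: 1
    odds_ratio: 0.65
  - predictor: baseline_egfr
    kind: continuous
    scale: 10
    degree: 2
    odds_ratio: 1.03
  - predictor: cancer
    kind: binary
    odds_ratio: 1.9
  - predictor: cardiac_failure
    kind: binary
    odds_ratio: 1.18
  - predictor: diabetes
    kind: binary
    odds_ratio: 1.21
  - predictor: pulmonary
    kind: binary
    odds_ratio: 1.46
metadata:
  setting: "Grampian 2012 external validation cohort (published refit)"
  risk_threshold: 0.30
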