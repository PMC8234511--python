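# Alberta 1-year CKD G4-G5 progression model, published refitted
# validation coefficient set (Grampian 2011-2013).  Same term structure
# and codings as the original model.
name: alberta_refit
outcome: ckd_g45_1y
intercept: -8.755
terms:
  - predictor: age
    kind: continuous
    scale: 1
    degree: 1
    odds_ratio: 1.02
  - predictor: female
    kind: binary
    odds_ratio: 3.05
  - predictor: aki_stage
    kind: categorical
    reference: "1"
    odds_ratios:
      "2": 2.15
      "3": 2.82
  - predictor: baseline_scr
    kind: continuous
    scale: 0.1
    degree: 1
    odds_ratio: 1.21
  - predictor: discharge_scr_cat
    kind: categorical
    reference: "<1.0"
    odds_ratios:
      "1.0-<1.3": 4.1
      "1.3-<1.6": 7.92
      "1.6-<1.9": 11.31
      ">1.9": 21.74
  - predictor: albuminuria
    kind: categorical
    reference: normal
    odds_ratios:
      mild: 0.95
      heavy: 2.00
      unmeasured: 0.78
metadata:
  setting: "Grampian 2011-2013 external validation cohort (published refit)"
  risk_thresholds: [0.01, 0.10]
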