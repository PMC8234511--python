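# Alberta 1-year CKD G4-G5 progression model for AKI survivors with
# baseline eGFR > 45, original derivation coefficient set.  The published
# discharge-creatinine reference category is printed "<0.1 mg/dL"; this is
# treated as a typographical error for "<1.0 mg/dL", consistent with the
# published cohort characteristic categories.
name: alberta_original
outcome: ckd_g45_1y
intercept: -9.246
terms:
  - predictor: age
    kind: continuous
    scale: 1
    degree: 1
    odds_ratio: 1.02
  - predictor: female
    kind: binary
    odds_ratio: 2.93
  - predictor: aki_stage
    kind: categorical
    reference: "1"
    odds_ratios:
      "2": 1.28
      "3": 2.47
  # Baseline serum creatinine, per 0.1 mg/dL greater.
  - predictor: baseline_scr
    kind: continuous
    scale: 0.1
    degree: 1
    odds_ratio: 1.18
  - predictor: discharge_scr_cat
    kind: categorical
    reference: "<1.0"
    odds_ratios:
      "1.0-<1.3": 2.93
      "1.3-<1.6": 7.78
      "1.6-<1.9": 11.35
      ">1.9": 37.01
  # "Unmeasured" is a genuine albuminuria level, not missing data.
  - predictor: albuminuria
    kind: categorical
    reference: normal
    odds_ratios:
      mild: 1.25
      heavy: 3.13
      unmeasured: 1.67
metadata:
  setting: "Alberta derivation cohort"
  risk_thresholds: [0.01, 0.10]
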