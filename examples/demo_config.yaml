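# Demo study: two arms, quarterly surveillance 19 -> ~34 months,
# exponential mortality, fractures possible after 24 months.
seed: 11
design:
  n_per_sex_per_arm: 12
  treatments: [control, HBX]
  max_age_days: 943.0        # 578 + 4 quarterly intervals
  fracture_hazard_per_day: 0.0002
mortality:
  family: exponential
  rate: 0.0016
traits:
  - phenotype: BV.TV          # percent bone volume, % units
    beta0: 55.0
    beta1_sex: 2.0
    beta3_slope: -1.941       # control decline per 100 days
    beta4_interaction: {HBX: 0.604}
    sd_intercept: 3.0
    sd_slope: 0.5
    sd_residual: 1.5
  - phenotype: tortuosity     # spinal curvature score, unitless
    beta0: 0.15
    beta3_slope: 0.01
    sd_intercept: 0.02
    sd_slope: 0.003
    sd_residual: 0.01
power:
  effects: [10.0, 15.0, 25.0]
  visits: [3, 5, 7]
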