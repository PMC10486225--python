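cohort:
  strata:
  - age_band: 15-24
    sex: female
    count: 4068
  - age_band: 15-24
    sex: male
    count: 2712
  - age_band: 25-34
    sex: female
    count: 3390
  - age_band: 25-34
    sex: male
    count: 2260
  - age_band: 35-44
    sex: female
    count: 2712
  - age_band: 35-44
    sex: male
    count: 1808
  - age_band: 45-64
    sex: female
    count: 2305
  - age_band: 45-64
    sex: male
    count: 1537
  - age_band: 65+
    sex: female
    count: 1085
  - age_band: 65+
    sex: male
    count: 723
  population_basis: 20000000
  admission_rate_per_100k: 113.0
transitions:
  p_repeat_nonfatal:
  - 0.163
  - 0.13040000000000002
  - 0.10432000000000001
  - 0.08345600000000002
  - 0.06676480000000001
  - 0.053411840000000016
  - 0.04272947200000002
  - 0.034183577600000015
  - 0.02734686208000001
  - 0.02187748966400001
  p_suicide:
  - 0.016
  - 0.0128
  - 0.01024
  - 0.008192000000000001
  - 0.0065536000000000014
  - 0.005242880000000002
  - 0.004194304000000002
  - 0.0033554432000000014
  - 0.002684354560000001
  - 0.0021474836480000013
  p_other_death:
  - 0.0005
  - 0.00075
  - 0.0008
  - 0.0012000000000000001
  - 0.0015
  - 0.0022500000000000003
  - 0.004
  - 0.006
  - 0.02
  - 0.03
effect:
  odds_ratio:
    kind: lognormal_from_ci
    point_value: 0.69
    ci_low: 0.55
    ci_high: 0.87
  decay:
    mode: halving_5yr
  uptake: 0.733
costs:
  intervention_unit_cost:
    kind: uniform_pct
    point_value: 615.0
    pct_halfwidth: 0.2
  healthcare_cost_per_selfharm_episode:
    kind: uniform_pct
    point_value: 6000.0
    pct_halfwidth: 0.2
  suicide_death_cost:
    kind: uniform_pct
    point_value: 714681.0
    pct_halfwidth: 0.2
  vsl:
    kind: point
    point_value: 4500000.0
  discount_rate: 0.03
utilities:
  u_no_selfharm:
    kind: beta_from_ci
    point_value: 0.64
    ci_low: 0.33
    ci_high: 0.95
  u_selfharm:
    kind: beta_from_ci
    point_value: 0.54
    ci_low: 0.29
    ci_high: 0.79
  constraint_delta: 0.1
  U_DEAD: 0.0
settings:
  horizon_years: 10
  wtp_threshold: 50000.0
  psa_iterations: 3000
  rng_seed: 2018
  price_year: 2018
  suicide_valuation: weighted_average
  effect_on_suicide: true
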