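schema_version: 1
name: vericiguat_base_case
# Two-arm cost-utility scenario: add-on vericiguat vs. standard treatment for
# chronic HFrEF in China.  All monetary values are 2022 CNY; all probabilities
# and utilities are per 3-month cycle and stored as fractions.
horizon_years: 13.0
cycle_length_years: 0.25
baseline_age: 67.3
discount_rate_annual: 0.05
wtp_per_qaly: 257100.0
initial_distribution: [0.0, 0.590, 0.397, 0.013]
transition_matrix:
- [0.977, 0.019, 0.004, 0.000]
- [0.008, 0.981, 0.010, 0.001]
- [0.000, 0.034, 0.960, 0.006]
- [0.000, 0.000, 0.055, 0.945]
background_mortality:
- {age_low: 68.0, age_high: 70.0, p_noncv: 0.00244}
- {age_low: 71.0, age_high: 75.0, p_noncv: 0.00312}
- {age_low: 76.0, age_high: 80.0, p_noncv: 0.00450}
utilities:
  u_by_state: [0.2138, 0.1865, 0.1485, 0.1408]
  disutility_by_state: [-0.01, -0.02, -0.03, -0.07]
arms:
  standard:
    events: {p_cv_death: 0.0256, p_hosp: 0.0929, p_readmit: 0.7885}
    costs:
      c_standard_cycle: 994.93
      c_arm_first_cycle: 994.93
      c_arm_later_cycle: 994.93
      c_hosp_by_state: [7624.03, 28657.14, 53589.71, 46659.46]
      inflation_factors: [1.043, 1.024, 1.018, 1.004, 1.006]
  vericiguat:
    events: {p_cv_death: 0.0233, p_hosp: 0.0849, p_readmit: 0.7699}
    costs:
      c_standard_cycle: 994.93
      # 994.93 basic regimen + 3892.84 titrated add-on drug
      c_arm_first_cycle: 4887.77
      # 994.93 basic regimen + 4872.00 maintenance add-on drug
      c_arm_later_cycle: 5866.93
      c_hosp_by_state: [7624.03, 28657.14, 53589.71, 46659.46]
      inflation_factors: [1.043, 1.024, 1.018, 1.004, 1.006]
pricing:
  box_5mg_cny: 406.0
  box_2_5mg_cny: 238.84
  boxes_first_cycle_2_5mg: 1.0
  boxes_first_cycle_5mg: 9.0
  boxes_later_cycle_5mg: 12.0
distributions:
  vericiguat.p_cv_death: {kind: beta, alpha: 2.33, beta: 97.67, low: 0.0221, high: 0.0245}
  vericiguat.p_hosp: {kind: beta, alpha: 8.49, beta: 91.51, low: 0.0807, high: 0.0891}
  standard.p_cv_death: {kind: beta, alpha: 2.56, beta: 97.44, low: 0.0243, high: 0.0269}
  standard.p_hosp: {kind: beta, alpha: 9.29, beta: 90.71, low: 0.0883, high: 0.0975}
  cost.standard_cycle: {kind: gamma, mean: 994.93, sd: 50.76, low: 895.44, high: 1094.42}
  cost.vericiguat_cycle: {kind: gamma, mean: 5866.93, sd: 299.33, low: 5280.24, high: 6453.62}
  cost.hosp_nyha1: {kind: gamma, mean: 7624.03, sd: 388.98, low: 6861.63, high: 8386.43}
  cost.hosp_nyha2: {kind: gamma, mean: 28657.14, sd: 1462.10, low: 25791.43, high: 31522.85}
  cost.hosp_nyha3: {kind: gamma, mean: 53589.71, sd: 2734.17, low: 48230.74, high: 58948.68}
  # The probabilistic mean (42488.95) deliberately differs from the
  # deterministic base admission cost for NYHA IV (46659.46); see notes.
  cost.hosp_nyha4: {kind: gamma, mean: 42488.95, sd: 2380.58, low: 41993.52, high: 51325.41}
  utility.nyha1: {kind: beta, alpha: 21.38, beta: 78.62, low: 0.2113, high: 0.2160}
  utility.nyha2: {kind: beta, alpha: 18.65, beta: 81.35, low: 0.1803, high: 0.1930}
  utility.nyha3: {kind: beta, alpha: 14.85, beta: 85.15, low: 0.1363, high: 0.1610}
  utility.nyha4: {kind: beta, alpha: 14.08, beta: 85.92, low: 0.1288, high: 0.1525}
  discount_rate: {kind: fixed, value: 0.05, low: 0.0, high: 0.08}
  # Transition rows: Dirichlet with pseudo-count 100 (concentration = row x 100),
  # the same convention as the Beta event-probability parameterisations.
  transition.nyha1: {kind: dirichlet, concentration: [97.7, 1.9, 0.4, 0.0]}
  transition.nyha2: {kind: dirichlet, concentration: [0.8, 98.1, 1.0, 0.1]}
  transition.nyha3: {kind: dirichlet, concentration: [0.0, 3.4, 96.0, 0.6]}
  transition.nyha4: {kind: dirichlet, concentration: [0.0, 0.0, 5.5, 94.5]}
notes:
  nyha4_hosp_cost_inconsistency: >-
    The source tables print 46659.46 as the deterministic NYHA IV admission
    cost but parameterise its uncertainty as Gamma with mean 42488.95 and SD
    2380.58.  Both values are carried: the deterministic base case uses
    46659.46, probabilistic draws use the Gamma exactly as published.
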