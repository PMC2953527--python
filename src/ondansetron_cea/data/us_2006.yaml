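# United States scenario, 2006 US$.
# Efficacy: meta-analytic event probabilities per arm with 95% CI sensitivity
# ranges. Costs: administrative/fee-schedule unit costs with +/-25% ranges.
name: us_2006
efficacy:
  ondansetron:
    p_vomit: {mean: 0.15, low: 0.10, high: 0.19, dist: normal}
    p_iv_given_vomit: {mean: 0.41, low: 0.25, high: 0.58, dist: normal}
    p_iv_given_no_vomit: {mean: 0.04, low: 0.01, high: 0.08, dist: normal}
    p_admit_given_iv: {mean: 0.23, low: 0.08, high: 0.37, dist: normal}
    p_revisit: {mean: 0.12, low: 0.08, high: 0.17, dist: normal}
    p_admit_at_revisit: {mean: 0.44, low: 0.26, high: 0.65, dist: gamma}
    p_redose: {mean: 0.05, low: 0.01, high: 0.09, dist: normal}
  control:
    p_vomit: {mean: 0.36, low: 0.30, high: 0.42, dist: normal}
    p_iv_given_vomit: {mean: 0.47, low: 0.35, high: 0.58, dist: normal}
    p_iv_given_no_vomit: {mean: 0.15, low: 0.08, high: 0.22, dist: normal}
    p_admit_given_iv: {mean: 0.30, low: 0.20, high: 0.41, dist: normal}
    p_revisit: {mean: 0.10, low: 0.06, high: 0.15, dist: normal}
    p_admit_at_revisit: {mean: 0.29, low: 0.13, high: 0.51, dist: gamma}
    p_redose: {mean: 0.0, low: 0.0, high: 0.0, dist: point}
costs:
  currency: USD
  base_year: 2006
  # 25% of ED visits in the SEDD cost mean included IV rehydration; the
  # embedded IV cost is removed since the tree bills IV insertion explicitly.
  ed_embedded_iv_fraction: 0.25
  hospitalization: {mean: 7539, low: 5654, high: 9424, dist: normal}
  ed_visit_mean: {mean: 704, low: 528, high: 879, dist: normal}
  physician_inpatient: {mean: 273, low: 205, high: 341, dist: normal}
  physician_ed: {mean: 61.31, low: 45.98, high: 76.64, dist: normal}
  iv_insertion: {mean: 194, low: 145, high: 243, dist: normal}
  ondansetron_dose: {mean: 26.57, low: 19.93, high: 33.21, dist: normal}
  wage_per_hour: {mean: 19.29, low: 14.47, high: 24.11, dist: normal}
  special_food_ors: {mean: 24.00, low: 18.00, high: 30.00, dist: normal}
  extra_diapers: {mean: 9.00, low: 6.75, high: 11.25, dist: normal}
  travel: {mean: 19.00, low: 14.25, high: 23.75, dist: normal}
population:
  country: US
  annual_ed_visits: 1725493
  eligibility_fraction: 0.10
utilities: {moderate: 0.93, severe: 0.90}
exchange_rate: {usd_per_cad: 0.88, low: 0.80, high: 1.00}
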