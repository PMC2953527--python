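# Canada scenario, 2006 CDN$. Efficacy probabilities are shared with the US
# scenario (same trials); unit costs are Canadian. The ondansetron dose price
# here is the costing-table value (12.86); a variant scenario carries the
# provincial drug-benefit average (13.09).
name: canada_2006_provincial_price
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
  currency: CAD
  base_year: 2006
  ed_embedded_iv_fraction: 0.0
  hospitalization: {mean: 955, low: 716, high: 1194, dist: normal}
  ed_visit_mean: {mean: 189, low: 141, high: 236, dist: normal}
  physician_inpatient: {mean: 183, low: 137, high: 228, dist: normal}
  physician_ed: {mean: 40.93, low: 30.70, high: 51.16, dist: normal}
  iv_insertion: {mean: 84, low: 63, high: 106, dist: normal}
  ondansetron_dose: {mean: 13.09, low: 9.82, high: 16.36, dist: normal}
  wage_per_hour: {mean: 18.55, low: 13.91, high: 23.19, dist: normal}
  special_food_ors: {mean: 27.27, low: 20.45, high: 34.09, dist: normal}
  extra_diapers: {mean: 10.23, low: 7.67, high: 12.78, dist: normal}
  travel: {mean: 21.59, low: 16.19, high: 26.98, dist: normal}
population:
  country: Canada
  annual_ed_visits: 239813
  eligibility_fraction: 0.10
utilities: {moderate: 0.93, severe: 0.90}
exchange_rate: {usd_per_cad: 0.88, low: 0.80, high: 1.00}
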