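# Base-case model inputs, 2019 SEK.  Unit costs for "diagnosis" and
# "screening_admin" carry the unrounded values implied by the published
# cost ledger (the input table prints them rounded to 785 and 165,000).
cohort_size: 2025
cohort_men: 930
cohort_women: 1095
discount_rate: 0.03
horizon_years: 20
unit_costs:
  dental_bp_test: 117.0
  phc_bp_test: 149.0
  ecg: 75.0
  lab: 240.0
  diagnosis: 784.0
  screening_admin: 165343.0
  ami_first_year: 112000.0
  ami_post_annual: 2670.0
  stroke_first_year: 112000.0
  stroke_post_annual: 85000.0
  drug_annual: 2150.0
  patient_hour: 160.0
  travel_trip: 6.5
case_fatality_365d:
  stroke: {men: 0.102, women: 0.144}
  ami: {men: 0.144, women: 0.173}
added_mortality:
  post_stroke: {men: 0.074, women: 0.061}
  post_ami: {men: 0.018, women: 0.017}
qaly_decrements:
  stroke_year: 0.50
  post_stroke: 0.25
  ami_year: 0.25
  post_ami: 0.05
sbp_untreated_hypertensive: 147.0
sbp_treated_hypertensive: 140.0
sbp_normotensive: 131.0
tc_hdl_ratio: {men: 4.0, women: 3.2}
identified_cases_screening: 170.0
identified_cases_se: 17.0
identified_cases_comparator_true: 46.0
comparator_false_positives: 15.0
comparator_total_diagnosed: 61.0
sek_per_eur: 10.3
mi_endpoint: mi
half_cycle_correction: false
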