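# Packaged worked-example scenario: 100,000 patients with diabetes,
# CDC segment shares, health-system engagement rates, national payer mix.
cohort:
  total_population: 100000
  segment_fractions:
    controlled: 0.50
    moderately_controlled: 0.355
    uncontrolled: 0.145
  overdue_rate:
    controlled: 0.131
    moderately_controlled: 0.298
    uncontrolled: 0.611
  no_future_visit_rate:
    controlled: 0.962
    moderately_controlled: 0.867
    uncontrolled: 0.756

payer_mix:
  commercial: 0.663
  medicare: 0.205
  medicaid: 0.132

policies:
  controlled: {visits_per_year: 1, overdue_lookback_months: 11, future_window_months: 3}
  moderately_controlled: {visits_per_year: 2, overdue_lookback_months: 5, future_window_months: 3}
  uncontrolled: {visits_per_year: 4, overdue_lookback_months: 2, future_window_months: 3}

catalog: packaged        # calibrated CPT catalog (or a CSV path)
fee_schedule: packaged   # calibrated per-payer fee schedule (or a CSV path)

uptake:
  uptake_fraction: 0.10  # conservative appointment-attendance estimate

conversion_factor: 41.94 # MGMA median, dollars per work RVU

inpatient:
  hospitalization_rate: 0.339   # 339 per 1000 people with diabetes per year
  per_payer_reimbursement:
    commercial: 2700.0
    medicare: 2000.0
    medicaid: 1280.0
  mix_mode: payer_proportional
  count_rounding: floor

rounding: half_up
revenue_basis: engaged
attended_basis: engaged_patients
seed: 0
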