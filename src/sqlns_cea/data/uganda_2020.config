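design:
  start_age_months: 6
  duration_months: 12
  sachets_per_day: 1
  sachet_mass_g: 20.0
  deliveries_per_year: 4
  start_year: 2021
  horizon_years: 10
  startup_years: 1
outcomes:
- name: mortality
  baseline: 0.0122
  relative_reduction: 0.27
  effect_window:
  - 6
  - 18
  counted_in_dalys: true
  disability_weight: 1.0
  disability_duration_years: remaining_life_expectancy
- name: anaemia_mod_sev
  baseline:
    6-9: 0.59
    9-18: 0.41
    18-24: 0.31
  relative_reduction: 0.28
  effect_window:
  - 9
  - 24
  counted_in_dalys: true
  disability_weight: 0.061700000000000005
  disability_duration_years: 1.25
- name: developmental_disability
  baseline: 0.0656
  relative_reduction: 0.16
  effect_window:
  - 18
  - 24
  counted_in_dalys: true
  disability_weight: 0.011
  disability_duration_years: remaining_life_expectancy
- name: stunting
  baseline: 0.42
  relative_reduction: 0.12
  effect_window:
  - 6
  - 18
  counted_in_dalys: false
- name: wasting_cross_sectional
  baseline: 0.078
  relative_reduction: 0.14
  effect_window:
  - 6
  - 18
  counted_in_dalys: false
- name: wasting_longitudinal
  baseline: 0.078
  relative_reduction: 0.3
  effect_window:
  - 6
  - 18
  counted_in_dalys: false
  correction_factors:
  - 2.6
  - 6.0
costs:
  price_per_carton_usd: 33.3
  sachets_per_carton: 546
  intl_shipping_usd_per_kg: 0.31
  customs_usd_per_kg: 1.01
  domestic_usd_per_kg: 0.17
  vht_incentive_usd_per_delivery: 0.44
  deflator_table: {}
discount:
  rate: 0.03
  reference_year: 2021
life_table:
  remaining_life_expectancy_years: 62.5
anaemia_severity_split:
- 0.9
- 0.1
anaemia_person_base: band_occupancy
scenario_name: base
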