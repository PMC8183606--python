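# Alternative parameter set re-derived from the most recent unscreened birth
# cohort (births from 2000 on): clinical awareness and ICU use differ from the
# base column; epidemiology, screening performance and unit costs stay at base.
scenario_name: group3_2000
epidemiology:
  live_births: 2923535
  cah_incidence: "1/12250"
  sw_fraction: 0.75
  clinical_recognition_sw: 0.13
  clinical_recognition_sv: 0.11
  sw_mortality_unscreened: 0.05
  life_expectancy_years: 76
  discount_rate: 0.03
  discounted_ly_per_death: 30.2
screening:
  fp_rate: 0.002
  high_risk_fraction: 0.25
  low_risk_fraction: 0.75
  confirmatory_fp_fraction: 0.08
  retest_fp_fraction: 0.005
sw:
  hosp_rate_screened: 0.58
  icu_rate_screened: 0.30
  icu_days_screened: 9
  hosp_rate_unscreened: 0.90
  icu_rate_unscreened: 0.61
  icu_days_unscreened: 20
sv:
  gh_use_rate: 0.40
  gh_years: 3.9
  gh_dose_ui_per_day: 5.09
  female_fraction: 0.5
  masculinization_rate: 0.11
  gnrha_use_rate: 0.30
  gnrha_years: 5.1
costs:
  ward_hospitalization: 70.8
  icu_day: 155.9
  screen_test_A: 2.45
  confirm_consult_B: 22.46
  gh_ampoule_price: 33.97
  gh_ampoule_ui: 12
  gnrha_ampoule_price: 273.75
  masculinization: 1906.19
  diagnostic_lab: 15.05
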