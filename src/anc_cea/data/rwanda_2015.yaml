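# Rwanda 2015 reference run configuration.
# Unit costs and epidemiology inputs are 2015 values; the maternal age
# distribution is synthetic, calibrated to 4044/195 discounted years per
# maternal death (see docs/methods.md).
label: rwanda-2015
variant: implied
seed: 20150
n_replications: 100
cohort_size: 373679
schedules:
- label: four-visit
  unit_costs_usd:
  - 21.0
  - 6.0
  - 6.0
  - 11.0
  overflow_visit_cost_usd: 6.0
- label: eight-visit
  unit_costs_usd:
  - 24.0
  - 6.0
  - 10.0
  - 6.0
  - 6.0
  - 10.0
  - 6.0
  - 11.0
  overflow_visit_cost_usd: 6.0
attendance_scenarios:
- label: scenario-1
  schedule: eight-visit
  mean_visits: 5.0
  sd_visits: 0.8
  min_visits: 1
  max_visits: 8
  degenerate: false
  include_in_cea: true
- label: scenario-2
  schedule: eight-visit
  mean_visits: 6.0
  sd_visits: 0.8
  min_visits: 2
  max_visits: 10
  degenerate: false
  include_in_cea: true
- label: scenario-3
  schedule: eight-visit
  mean_visits: 7.0
  sd_visits: 0.8
  min_visits: 3
  max_visits: 11
  degenerate: false
  include_in_cea: true
- label: full-utilisation
  schedule: four-visit
  mean_visits: 4.0
  sd_visits: 0.0
  min_visits: 4
  max_visits: 4
  degenerate: true
  include_in_cea: false
outcomes:
  source: explicit
  expert_csv: null
  scenarios:
  - label: pessimistic
    perinatal_reduction_pct: 22.5
    maternal_reduction_pct: 7.0
  - label: optimistic
    perinatal_reduction_pct: 55.0
    maternal_reduction_pct: 52.5
baseline:
  annual_perinatal_deaths: 10076
  annual_maternal_deaths: 371
  life_expectancy_both_sexes_years: 64.0
  life_expectancy_female_years: 66.0
  discount_rate: 0.03
  maternal_age_distribution:
  - midpoint_years: 17.5
    share: 0.04491419893139827
  - midpoint_years: 22.5
    share: 0.13485699821899713
  - midpoint_years: 27.5
    share: 0.19491419893139827
  - midpoint_years: 32.5
    share: 0.22497139964379942
  - midpoint_years: 37.5
    share: 0.2101144014248023
  - midpoint_years: 42.5
    share: 0.1401144014248023
  - midpoint_years: 47.5
    share: 0.05011440142480231
  perinatal_mortality_rate_per_1000: 29.0
  maternal_mortality_ratio_per_100k: 210.0
cea:
  comparator_total_cost_usd: 13939970.0
  comparator_cost_per_woman_usd: 37.0
  gdp_per_capita_usd: 697.0
  very_ce_multiplier: 1.0
  not_ce_multiplier: 3.0
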