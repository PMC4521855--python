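# Demo synthetic market scenario: a 156-month (13-year) urban bushmeat
# market with three periods, a trap-to-shotgun transition, and external
# shocks hitting the primate group on the sqrt scale.
start_month: "1997-10"
n_months: 156
seed: 0
period_starts: ["2003-04", "2007-11"]
count_model: poisson
market_days:
  base: 26
  max_dropout: 4
  dropout_prob: 0.25
noise:
  order: [2, 0, 0]
  seasonal_order: [1, 0, 0, 12]
  ar: [0.343, 0.301]
  seasonal_ar: [0.208]
  mean: 2.0
  sigma: 0.323
interventions:
  - event_month: "1998-02"
    pulse_weight: -1.357
    target_groups: [primate]
  - event_month: "2002-03"
    step_weight: 0.457
    pulse_weight: -0.625
    target_groups: [primate]
  - event_month: "2003-11"
    step_weight: -1.001
    pulse_weight: 3.037
    target_groups: [primate]
  - event_month: "2007-11"
    step_weight: 3.037
    pulse_weight: -5.202
    lag_delta: 0.945
    target_groups: [primate]
species:
  - name: Synthetic guenon
    group: primate
    mass_kg: 3.4
    island_proportion: 1.0
    baseline_rate: 4.0
    trend_per_month_by_period: [0.01, 0.09, 0.0]
    shotgun_probability_by_period: [0.85, 0.95, 0.99]
    seasonal_amplitude: 0.15
    seasonal_phase: 3.0
  - name: Synthetic pouched rat
    group: rodent
    mass_kg: 1.14
    island_proportion: 1.0
    baseline_rate: 8.0
    trend_per_month_by_period: [0.06, 0.2, -0.2]
    shotgun_probability_by_period: [0.1, 0.3, 0.45]
    seasonal_amplitude: 0.1
    seasonal_phase: 0.0
  - name: Synthetic duiker
    group: ungulate
    mass_kg: 4.9
    island_proportion: 0.95
    baseline_rate: 7.0
    trend_per_month_by_period: [0.02, 0.12, 0.14]
    shotgun_probability_by_period: [0.5, 0.7, 0.85]
    seasonal_amplitude: 0.12
    seasonal_phase: 6.0
  - name: Synthetic porcupine
    group: rodent
    mass_kg: 2.83
    island_proportion: 0.9
    baseline_rate: 5.0
    trend_per_month_by_period: [0.03, 0.1, -0.1]
    shotgun_probability_by_period: [0.2, 0.4, 0.5]
    seasonal_amplitude: 0.1
    seasonal_phase: 9.0
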