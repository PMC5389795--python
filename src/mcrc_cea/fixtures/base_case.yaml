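# Published Brazilian public-payer (SUS) base case: cetuximab and
# panitumumab monotherapy versus best supportive care (BSC) in
# chemotherapy-refractory RAS-wild-type metastatic colorectal cancer.
# All monetary values are USD (BRL converted at 3.50 by the source;
# the rate is metadata only and never applied at runtime).
#
# Known cent-level inconsistencies in the published inputs, stored as
# printed and cross-checked (not silently corrected):
#   - WTP threshold is printed 24,751 although 3 x 8,250 = 24,750.
#   - Panitumumab vial price: 270.43 (dosing table) vs 270.42
#    (sensitivity-range table); the base case uses 270.43 and the
#    one-way range uses 270.42, both as printed.
#   - Panitumumab quarterly drug cost prints 8,112.70 but 6 x 5 vials
#    x 270.43 = 8,112.90; the printed state total 8,442.82 matches
#    neither its own column sum (8,442.64) nor the recomputed 8,442.84.
#   - Panitumumab dose-reduction need is 17.5% in the text but 0.18 in
#    the sensitivity-range table; the range table value is used below
#    for the one-way baseline.
schema_version: 1
name: base_case
economics:
  cycle_length_years: 0.25
  annual_discount_rate: 0.05
  gdp_per_capita_usd: 8250.0
  wtp_threshold_usd_per_ly: 24751.0
  exchange_rate_brl_per_usd: 3.50
  horizon_max_cycles: 200
  extinction_tolerance: 1.0e-9
conventions:
  life_years: half_cycle
  costs: half_cycle
strategies:
- name: BSC
  transitions:
    p_death_bsc: 0.36
  costs:
    resources:
      outpatient: 27.63
      laboratory: 11.86
      imaging: 2.71
      hospitalization: 104.98
    printed_state_total_usd: 147.18
- name: panitumumab
  transitions:
    p_progress: 0.29
    p_death_on_tx: 0.20
    p_death_bsc: 0.36
    p_dose_reduction: 0.175
  costs:
    dose_schedule:
      dose_basis: per_weight
      dose_mg: 6.0
      body_weight_kg: 70.0
      vial_size_mg: 100.0
      vial_unit_price_usd: 270.43
      administrations_per_cycle: 6
    resources:
      outpatient: 27.94
      laboratory: 15.68
      imaging: 118.19
      hospitalization: 168.13
    adverse_events:
      average_cycle_cost_usd: 63.34
      events:
      - {name: diarrhea, probability: 0.020}
      - {name: abdominal_pain, probability: 0.034}
      - {name: vomiting, probability: 0.018}
      - {name: anemia, probability: 0.026}
      - {name: dyspnea, probability: 0.010}
      - {name: upper_respiratory_tract_infection, probability: 0.004}
      - {name: infusion_reactions, probability: 0.002}
    dose_reduction_fraction: 0.0
    printed_moab_cycle_cost_usd: 8112.70
    printed_state_total_usd: 8442.82
- name: cetuximab
  transitions:
    p_progress: 0.29
    p_death_on_tx: 0.20
    p_death_bsc: 0.36
    p_dose_reduction: 0.18
  costs:
    dose_schedule:
      dose_basis: per_body_surface
      dose_mg: 500.0
      body_surface_m2: 1.75
      vial_size_mg: 100.0
      vial_unit_price_usd: 166.70
      administrations_per_cycle: 6
    resources:
      outpatient: 27.94
      laboratory: 15.68
      imaging: 118.19
      hospitalization: 171.82
    adverse_events:
      average_cycle_cost_usd: 66.84
      events:
      - {name: diarrhea, probability: 0.018}
      - {name: abdominal_pain, probability: 0.028}
      - {name: vomiting, probability: 0.014}
      - {name: anemia, probability: 0.030}
      - {name: dyspnea, probability: 0.014}
      - {name: upper_respiratory_tract_infection, probability: 0.0}
      - {name: infusion_reactions, probability: 0.018}
    dose_reduction_fraction: 0.0
    printed_moab_cycle_cost_usd: 9001.80
    printed_state_total_usd: 9335.43
sensitivity:
  ranges:
  - {parameter: p_progress, baseline: 0.29, low: 0.22, high: 0.36, strategy: panitumumab}
  - {parameter: p_death_on_tx, baseline: 0.20, low: 0.15, high: 0.25, strategy: panitumumab}
  - {parameter: cetuximab.p_dose_reduction, baseline: 0.18, low: 0.14, high: 0.23}
  - {parameter: panitumumab.p_dose_reduction, baseline: 0.18, low: 0.13, high: 0.22}
  - {parameter: cetuximab.vial_unit_price, baseline: 166.70, low: 0.0, high: 166.70}
  - {parameter: panitumumab.vial_unit_price, baseline: 270.42, low: 0.0, high: 270.42}
  - {parameter: cetuximab.body_surface, baseline: 1.75, low: 1.60, high: 1.90}
  - {parameter: panitumumab.body_weight, baseline: 70.0, low: 50.0, high: 90.0}
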