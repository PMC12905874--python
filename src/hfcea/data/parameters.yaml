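# Model inputs: clinical probabilities, health-state utilities, and costs
# (2025 USD) for the one-year heart-failure adherence decision tree.
# Each record: base value, uncertainty range, how the range was stated
# (95% CI, assumed +/-25% or +/-50%, or a literature min-max), the sampling
# distribution family, and units.
parameters:
  - {name: p_good_adherence_usual,       base: 0.556,   low: 0.417,  high: 0.695,  basis: pct25,            family: beta,  units: probability}
  - {name: adherence_gain,               base: 0.185,   low: 0.093,  high: 0.278,  basis: pct50,            family: beta,  units: probability}
  - {name: p_exac_good,                  base: 0.232,   low: 0.174,  high: 0.289,  basis: pct25,            family: beta,  units: probability}
  - {name: p_exac_poor,                  base: 0.419,   low: 0.314,  high: 0.524,  basis: pct25,            family: beta,  units: probability}
  - {name: p_survive_exac,               base: 0.597,   low: 0.448,  high: 0.747,  basis: pct25,            family: beta,  units: probability}
  - {name: p_worsen,                     base: 0.150,   low: 0.113,  high: 0.188,  basis: pct25,            family: beta,  units: probability}
  - {name: p_survive_no_exac,            base: 0.865,   low: 0.854,  high: 0.876,  basis: ci95,             family: beta,  units: probability}
  - {name: u_exacerbation,               base: 0.560,   low: 0.555,  high: 0.565,  basis: ci95,             family: beta,  units: utility}
  - {name: u_stable,                     base: 0.780,   low: 0.775,  high: 0.785,  basis: ci95,             family: beta,  units: utility}
  - {name: u_worsened,                   base: 0.600,   low: 0.565,  high: 0.635,  basis: ci95,             family: beta,  units: utility}
  - {name: cost_intervention_year1,      base: 498,     low: 373,    high: 622,    basis: pct25,            family: gamma, units: usd}
  - {name: cost_intervention_subsequent, base: 400,     low: 300,    high: 500,    basis: pct25,            family: gamma, units: usd}
  - {name: cost_hospitalization,         base: 33851,   low: 6603,   high: 73382,  basis: literature_range, family: gamma, units: usd}
  - {name: cost_outpatient,              base: 1304,    low: 735,    high: 1872,   basis: literature_range, family: gamma, units: usd}
  - {name: cost_ed_visit,                base: 1997,    low: 1498,   high: 2497,   basis: pct25,            family: gamma, units: usd}
  - {name: cost_hf_medications,          base: 367,     low: 275,    high: 459,    basis: pct25,            family: gamma, units: usd}
  - {name: cost_worsening_medications,   base: 2893,    low: 1357,   high: 4430,   basis: literature_range, family: gamma, units: usd}
  - {name: cost_post_acute,              base: 4538,    low: 1521,   high: 7852,   basis: literature_range, family: gamma, units: usd}
constants:
  wtp_threshold: 150000
  n_psa_iterations: 1000
  death_month: 6
  exac_duration_months: 1
  hazard_ratio_nonadherent: 1.81
  cohort_age: 75
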