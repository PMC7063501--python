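# Base-case model inputs for the T1 colorectal cancer treatment model.
# All monetary values are 2019 USD. Probabilities are per month unless noted.
# family: beta | gamma | uniform | fixed   (fixed = not sampled in PSA)
# role:   probability | cost | utility | rate | setting

currency: 2019 USD

classes:
  class0: {label: "APCwt", hazard_ratio: 1.94, mortality_param: p_crcdeath_class0}
  class1: {label: "APC(1) / APC(1)+KRAS / APC(1)+TP53", hazard_ratio: 1.00, mortality_param: p_crcdeath_class1}
  class2: {label: "APC(2) / APC(2)+KRAS / APC(2)+TP53", hazard_ratio: 1.11, mortality_param: p_crcdeath_class2}
  class3: {label: "APC(1)+KRAS+TP53", hazard_ratio: 1.48, mortality_param: p_crcdeath_class3}
  class4: {label: "APC(2)+KRAS+TP53", hazard_ratio: 2.48, mortality_param: p_crcdeath_class4}
  msi_h:  {label: "BRAFV600E (MSI-H)", hazard_ratio: null, mortality_param: p_crcdeath_msi_h}

parameters:
  # ---- 30-day procedural mortality (per procedure) ----
  p_mort30_ET: {base: 0.0001, low: 0.000075, high: 0.000125, family: beta, units: probability, role: probability}
  p_mort30_OC: {base: 0.0100, low: 0.0075, high: 0.0125, family: beta, units: probability, role: probability}
  p_mort30_LC: {base: 0.0050, low: 0.00375, high: 0.00625, family: beta, units: probability, role: probability}

  # ---- Complications requiring readmission (per procedure) ----
  p_compl_ET: {base: 0.0100, low: 0.0075, high: 0.0125, family: beta, units: probability, role: probability}
  p_compl_OC: {base: 0.0500, low: 0.0375, high: 0.0625, family: beta, units: probability, role: probability}
  p_compl_LC: {base: 0.0400, low: 0.03, high: 0.05, family: beta, units: probability, role: probability}

  # ---- Intra-procedural conversion to emergency open colectomy ----
  p_convert_ET: {base: 0.0150, low: 0.0113, high: 0.0188, family: beta, units: probability, role: probability}
  p_convert_LC: {base: 0.1900, low: 0.1425, high: 0.2375, family: beta, units: probability, role: probability}

  # ---- Monthly probability of recurrent cancer, by index treatment ----
  p_recur_ET: {base: 0.0012, low: 0.0009, high: 0.0015, family: beta, units: probability/mo, role: probability}
  p_recur_OC: {base: 0.0006, low: 0.00045, high: 0.00075, family: beta, units: probability/mo, role: probability}
  p_recur_LC: {base: 0.0007, low: 0.000525, high: 0.000875, family: beta, units: probability/mo, role: probability}

  # ---- Monthly CRC-specific mortality in the recurrent-cancer state, by biomarker class ----
  p_crcdeath_class4: {base: 0.0119, low: 0.0089, high: 0.0149, family: beta, units: probability/mo, role: probability}
  p_crcdeath_class0: {base: 0.0074, low: 0.0056, high: 0.0093, family: beta, units: probability/mo, role: probability}
  p_crcdeath_msi_h: {base: 0.0028, low: 0.0028, high: 0.0028, family: fixed, units: probability/mo, role: probability}
  p_crcdeath_class3: {base: 0.0025, low: 0.0025, high: 0.0025, family: fixed, units: probability/mo, role: probability}
  p_crcdeath_class2: {base: 0.0024, low: 0.0024, high: 0.0024, family: fixed, units: probability/mo, role: probability}
  p_crcdeath_class1: {base: 0.0012, low: 0.0012, high: 0.0012, family: fixed, units: probability/mo, role: probability}

  # ---- One-time procedure costs (2019 USD) ----
  cost_ET: {base: 980, low: 490, high: 1960, family: gamma, units: USD, role: cost}
  cost_OC: {base: 44837, low: 22419, high: 89674, family: gamma, units: USD, role: cost}
  cost_LC: {base: 37778, low: 18889, high: 75556, family: gamma, units: USD, role: cost}
  # Net incremental cost of emergency open colectomy over the elective procedure already billed
  cost_emergency_after_ET: {base: 43857, low: 21929, high: 87714, family: gamma, units: USD, role: cost}
  cost_emergency_after_LC: {base: 7059, low: 3530, high: 14118, family: gamma, units: USD, role: cost}

  # ---- Recurring monthly costs (2019 USD / month) ----
  cost_surveillance_monthly: {base: 28, low: 14, high: 56, family: gamma, units: USD/mo, role: cost}
  # Recurrent-cancer treatment cost: one printed input, carried per index treatment so each
  # can be varied independently in sensitivity analyses.
  cost_recur_treatment_ET: {base: 3872, low: 1936, high: 7744, family: gamma, units: USD/mo, role: cost}
  cost_recur_treatment_OC: {base: 3872, low: 1936, high: 7744, family: gamma, units: USD/mo, role: cost}
  cost_recur_treatment_LC: {base: 3872, low: 1936, high: 7744, family: gamma, units: USD/mo, role: cost}

  # ---- One-time complication (readmission) costs ----
  cost_compl_bleeding: {base: 7493, low: 3747, high: 14986, family: gamma, units: USD, role: cost}
  cost_compl_obstruction: {base: 5671, low: 2836, high: 11342, family: gamma, units: USD, role: cost}

  # ---- Health-state utilities ----
  u_pre: {base: 0.88, low: 0.792, high: 0.968, family: uniform, units: utility, role: utility}
  u_ET_m1: {base: 0.82, low: 0.738, high: 0.902, family: beta, units: utility, role: utility}
  u_ET_post: {base: 0.95, low: 0.855, high: 1.000, family: beta, units: utility, role: utility}
  u_OC_m1: {base: 0.79, low: 0.711, high: 0.869, family: uniform, units: utility, role: utility}
  u_OC_post: {base: 0.91, low: 0.819, high: 1.000, family: beta, units: utility, role: utility}
  u_LC_m1: {base: 0.81, low: 0.729, high: 0.891, family: beta, units: utility, role: utility}
  u_LC_post: {base: 0.93, low: 0.837, high: 1.000, family: beta, units: utility, role: utility}
  u_emergency_m1: {base: 0.74, low: 0.666, high: 0.814, family: beta, units: utility, role: utility}
  u_emergency_post: {base: 0.91, low: 0.819, high: 1.000, family: beta, units: utility, role: utility}
  # Recurrent-cancer utility: one printed input, carried per index treatment (see cost note).
  u_recur_ET: {base: 0.75, low: 0.675, high: 0.825, family: beta, units: utility, role: utility}
  u_recur_OC: {base: 0.75, low: 0.675, high: 0.825, family: beta, units: utility, role: utility}
  u_recur_LC: {base: 0.75, low: 0.675, high: 0.825, family: beta, units: utility, role: utility}

  # ---- Analysis settings ----
  discount_rate_annual: {base: 0.03, low: 0.0, high: 0.05, family: fixed, units: /yr, role: setting}
  start_age_years: {base: 65, low: 55, high: 75, family: uniform, units: years, role: setting}
  max_age_years: {base: 100, low: 100, high: 100, family: fixed, units: years, role: setting}
  cycle_length_months: {base: 1, low: 1, high: 1, family: fixed, units: months, role: setting}
  wtp_per_qaly: {base: 100000, low: 0, high: 200000, family: fixed, units: USD/QALY, role: setting}
  # Structural switch (0/1): route ET/LC complications to emergency open
  # colectomy instead of pricing them as readmission cost events.
  complications_route_to_emergency: {base: 0, low: 0, high: 1, family: fixed, units: flag, role: setting}
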