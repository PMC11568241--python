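# Synthetic demonstration scenario (entirely fabricated data).
# Prevalence margins loosely echo the validation cohort's per-agent exposure
# shares so demo reports visually resemble a real validation table.
n_patients: 186
seed: 2013
diagnosis_year: 2013

agents:
  carboplatin: {modality: chemo, prevalence: 0.12, cycles: {4: 0.3, 6: 0.7}}
  cyclophosphamide: {modality: chemo, prevalence: 0.42, cycles: {4: 0.7, 6: 0.3}}
  docetaxel: {modality: chemo, prevalence: 0.32, cycles: {4: 0.6, 6: 0.4}}
  doxorubicin: {modality: chemo, prevalence: 0.21, cycles: {4: 0.9, 6: 0.1}}
  paclitaxel: {modality: chemo, prevalence: 0.18, cycles: {4: 0.5, 6: 0.5}}
  tamoxifen:
    {modality: endocrine, prevalence: 0.34, cycles: {6: 0.4, 8: 0.6},
     cycle_days: 30, start_offset_days: [60, 120]}
  anastrozole:
    {modality: endocrine, prevalence: 0.26, cycles: {6: 0.4, 8: 0.6},
     cycle_days: 30, start_offset_days: [60, 120]}
  letrozole:
    {modality: endocrine, prevalence: 0.11, cycles: {6: 0.4, 8: 0.6},
     cycle_days: 30, start_offset_days: [60, 120]}
  trastuzumab: {modality: biologic, prevalence: 0.13, cycles: {6: 0.5, 11: 0.5}}

sources:
  APCD: {sensitivity: 0.89, false_positive_rate: 0.05, date_dropout: 0.05}
  UCR_claims: {sensitivity: 0.28, false_positive_rate: 0.01}
  EMR: {sensitivity: 0.30, false_positive_rate: 0.01}
  SHFD: {sensitivity: 0.20, false_positive_rate: 0.01}

radiotherapy:
  prevalence: 0.55
  schedule_mix: {standard: 0.6, hypofractionated: 0.3, apbi: 0.1}
  incompletion_probability: 0.15
  interruption_probability: 0.10
  interruption_gap_days: [7, 21]
  start_offset_days: [100, 220]

abstraction_sensitivity: 0.95
abstraction_dose_noise_sd: 0.0
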