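# Guideline per-cycle doses used for cumulative dose reconstruction.
# The doxorubicin 60 mg/m2 and carboplatin AUC-6/21-day entries follow the
# published method; the other per-cycle doses are commonly recommended
# defaults and should be edited to match the regimens under study.
doxorubicin: {unit: mg_per_m2, dose_per_cycle: 60, cycle_days: 21}
docetaxel: {unit: mg_per_m2, dose_per_cycle: 75, cycle_days: 21}
cyclophosphamide: {unit: mg_per_m2, dose_per_cycle: 600, cycle_days: 21}
paclitaxel: {unit: mg_per_m2, dose_per_cycle: 175, cycle_days: 21}
carboplatin: {unit: auc, auc: 6, cycle_days: 21}
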