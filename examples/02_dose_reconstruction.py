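"""Cumulative chemotherapy dose from claim-identified cycles.

Each distinct service date is one cycle; the per-cycle dose comes from the
regimen table, scaled by Mosteller body surface area for mg/m2 agents or by
the Calvert equation (AUC 6, Cockcroft-Gault GFR) for carboplatin.
"""

from datetime import date

from claims2tx import (
    PatientProfile,
    cumulative_chemo_dose,
    default_regimen_table,
    mosteller_bsa,
)

profile = PatientProfile(
    patient_id="P1",
    diagnosis_date=date(2013, 3, 1),
    age_at_diagnosis=50,
    height_cm=180,
    weight_kg=80,
    serum_creatinine_mg_dl=0.8,
)
regimens = default_regimen_table()

print(f"BSA = {mosteller_bsa(profile.height_cm, profile.weight_kg):.2f} m2")
for agent, cycles in [("doxorubicin", 4), ("docetaxel", 6), ("carboplatin", 6)]:
    est = cumulative_chemo_dose(agent, cycles, profile, regimens)
    print(f"{agent:16s} {cycles} cycles -> {est.cumulative_dose:7.1f} mg ({est.method})")

# doxorubicin: 60 mg/m2 x 2.0 m2 x 4 cycles = 480 mg.
# carboplatin: 6 x (GFR + 25) mg per cycle via the Calvert equation, summed
# over cycles; GFR uses the Cockcroft-Gault female formula.
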