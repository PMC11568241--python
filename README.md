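# claims2tx

Reconstruct breast-cancer treatment from administrative billing claims, and
quantify how well the reconstruction agrees with gold-standard medical-record
abstraction.

Cancer registries often lack chemotherapy agent names, doses, and radiotherapy
detail. Statewide all-payer claims databases (APCDs) carry the billing trail of
care — HCPCS/CPT procedure codes on medical claims, NDC product codes on
pharmacy claims — and can fill that gap *if* claims-derived treatment variables
are valid. `claims2tx` implements the reconstruction and the validation
machinery for epidemiologists working with such data:

- **Identification** — map claim lines to agents through a user-editable code
  dictionary; one distinct service date = one chemotherapy cycle; exposure is
  confined to a window (default one year) after diagnosis; indicators can be
  built per data source and for arbitrary source unions.
- **Dose reconstruction** — cumulative dose = guideline per-cycle dose ×
  cycles, scaled by Mosteller body surface area
  (BSA = √(height·weight/3600)), or by the Calvert equation for carboplatin
  (dose = AUC × (GFR + 25), AUC 6, Cockcroft-Gault female GFR).
- **Radiotherapy** — delivery-code dates (planning codes excluded) are split
  into courses at gaps > 30 days; completion is classified against
  fractionation schedules (25–28 standard, 15–16 hypofractionated, 10 APBI);
  total Gy is assigned from the fraction count by a tiered rule
  (≤16 non-matching fractions × 2.67 Gy; 17–21 → 16×2.66 + rest×2.50;
  ≥22 × 2.0 Gy; no estimate under 5 fractions; capped at 66 Gy).
- **Agreement statistics** — 2×2 quadrants, Cohen's κ = (P₀−Pₑ)/(1−Pₑ) with
  an asymptotic (Fleiss) CI, sensitivity/specificity/PPV/NPV with Wald (or
  Wilson) 95% CIs, and the one-way random-effects intraclass correlation
  ICC = σ²_B/(σ²_B+σ²_W) for continuous doses, with an optional log
  transform.
- **Synthetic data** — a seeded generator producing matched truth,
  multi-source noisy claims, and abstraction records, so every stage is
  testable without restricted data.
- **Reporting** — an end-to-end pipeline rendering validation-style tables
  with small-cell suppression (counts < 11 masked, with complement
  suppression so row totals cannot restore them).

## Worked example

```python
from claims2tx import ContingencyTable, agreement_summary

t = ContingencyTable(both=62, gold_only=16, claims_only=12, neither=96)
res = agreement_summary(t)
print(f"kappa {100*res.kappa:.1f}%, sensitivity {100*res.sensitivity:.1f}% "
      f"(95% CI {100*res.sensitivity_ci[0]:.1f}, {100*res.sensitivity_ci[1]:.1f})")
```

prints

```
kappa 68.9%, sensitivity 79.5% (95% CI 70.5, 88.4)
```

i.e. substantial chance-corrected agreement: of the 78 abstraction-confirmed
exposures, the claims recovered 62 (79.5%), and 96 of the 108 true negatives
were correctly claim-negative (specificity 88.9%).

More narrative examples live in `examples/` (one script per capability:
agreement from published counts, dose reconstruction, radiotherapy courses,
synthetic round-trip validation, full suppressed report). A thin CLI wraps
the batch stages:

```bash
claims2tx simulate --seed 7 --out scratch/demo
claims2tx report --claims scratch/demo/claims.csv \
    --abstraction scratch/demo/abstraction.csv \
    --profiles scratch/demo/profiles.csv --out scratch/demo/report
```

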