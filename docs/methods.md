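# Methods

## Problem setting

Manual abstraction of treatment details from medical records is the gold
standard for oncology exposure data but is slow and expensive. Claims data
record the billing trail of care instead. `claims2tx` operationalises a
claims-based reconstruction of breast-cancer treatment — which agents a
patient received, how many cycles, at what cumulative dose, and whether a
radiotherapy course was completed and at what total dose — together with the
statistics used to validate such a reconstruction against abstraction.

## Identification model

A claim line is (patient, service date, billing code, source, claim type).
Codes resolve through a `CodeMap` after normalization (uppercase, strip
non-alphanumerics, so a typeset "77,401" matches HCPCS 77401). Pharmacy
claims are matched only against endocrine NDCs, medical claims only against
infusion-chemotherapy and biologic HCPCS/CPT codes; this gating prevents a
stray J-code on a pharmacy line from creating an exposure. NDCs match at the
9-digit labeler+product prefix by default (package-size digits vary across
claims feeds); exact 11-digit matching is available.

Exposure requires at least one matching claim in
`[diagnosis, diagnosis + window]`, window 365 days by default (primary
courses typically start within 3–4 months of diagnosis and conclude within a
year). Each **distinct** service date is one cycle — same-day duplicates
(multiple claim lines for one administration) collapse. Episodes carry the
set of contributing sources, so indicators can be computed per source and
for source unions; the union is a logical OR, hence enlarging a subset never
lowers sensitivity against a fixed gold standard. An explicit per-patient
exclusion list supports removing post-primary (beyond first course)
treatment, which is a manual judgement in practice.

The bundled code dictionary is an editable stand-in: the nine radiotherapy
delivery codes (77401, 77402, 77412, 77413, 77414, 77416, 77418, 77787,
77778) are fixed by the method, while the per-agent J-codes and NDCs are
best-effort defaults that users should replace with their own (CanMED-style)
lists, which evolve over time.

## Dose reconstruction

Cumulative chemotherapy dose is per-cycle dose × cycle count. For mg/m²
agents the per-cycle dose is the guideline dose scaled by Mosteller BSA
√(height_cm · weight_kg / 3600). Carboplatin uses the Calvert equation
(dose = AUC × (GFR + 25)) at the recommended target AUC 6 for 21-day
dosing, with the Cockcroft-Gault female GFR
0.85 · (140 − age) · weight / (72 · creatinine). Serum creatinine is rarely
present in claims extracts, so a fixed assumed value of 0.8 mg/dL is used by
default and is configurable per patient. The bundled regimen table carries
doxorubicin 60 mg/m² and carboplatin AUC 6 (method-defined) plus common
defaults for docetaxel (75), cyclophosphamide (600), and paclitaxel
(175 mg/m²); these are config entries, not constants. `use_bsa=False`
reports mg/m² agents unscaled, the sensitivity-analysis convention.

## Radiotherapy model

Fraction dates are the distinct delivery-code service dates in the window;
planning codes never count. Dates are split into courses wherever
consecutive fractions are more than 30 days apart (a larger gap would be an
abandoned/restarted treatment rather than an interruption); the first course
is the primary analysis unit. Completion is classified by a configurable
rule: ≥ 15 fractions (the hypofractionated minimum) is complete, as is a
dense ≥ 10-fraction course with all inter-fraction gaps ≤ 1 day (the
accelerated partial-breast pattern).

Total dose is assigned from the fraction count by a tiered rule: counts that
match a recognised schedule use that schedule's canonical dose per fraction
(15–16 × 2.66 Gy; 10 fractions → 34 Gy; both config entries); otherwise
≤ 16 fractions get 2.67 Gy each, 17–21 get 16 × 2.66 Gy + 2.50 Gy for the
remainder, and ≥ 22 get 2.0 Gy each. No dose is estimated below 5 fractions
and estimates are capped at 66 Gy. Note the rule is deliberately **not**
monotone in the fraction count across tier boundaries (e.g. 21 fractions →
55.06 Gy but 22 → 44 Gy): the tiers encode a judgement about which schedule
the count most plausibly represents, not a dose-response curve. Five
matching fractions have no published canonical dose and fall in the
2.67 Gy tier by default. An optional boost flag labels a later course
starting within a configurable number of days (> the 30-day gap) of the
initial course's end.

## Agreement statistics

Binary indicators are compared in a 2×2 table with the abstraction on the
rows. Cohen's κ = (P₀ − Pₑ)/(1 − Pₑ) with the Fleiss-Cohen-Everitt
asymptotic standard error for its CI; when Pₑ = 1 (degenerate margins) κ is
defined as 0 with a warning. Sensitivity, specificity, PPV and NPV get Wald
95% intervals p̂ ± 1.96·√(p̂(1−p̂)/m), clipped to [0, 1]; Wald is the default
because it back-calculates exactly from the validation literature this
package targets, with Wilson available via a flag. Zero-denominator metrics
are reported as missing rather than raising.

Dose agreement uses the one-way random-effects ICC with k = 2 ratings per
subject: σ²_B = max(0, (MSB − MSW)/2), σ²_W = MSW,
ICC = σ²_B/(σ²_B + σ²_W), truncated at 0. The CI uses the exact
F-distribution bounds for the one-way model (Shrout–Fleiss ICC(1)), clipped
to [0, 1] for consistency with the truncated point estimate. A natural-log
transform of both sides (strictly positive pairs required) is available to
reduce skew. Pairs with a missing side are dropped pairwise and counted.
Note that commercial software defaults (e.g. Stata's `kappaetc`) may fit a
different ICC model; this implementation follows the printed
variance-components formula and documents rather than emulates such
defaults.

## Synthetic-data generator

The generator emulates the data-generating world the validation assumes:
Bernoulli per-agent prevalence (defaults echo the 186-patient validation
cohort's margins, e.g. cyclophosphamide ≈ 0.42), cycle counts from a small
distribution laid out at 21-day (chemo) or 30-day (endocrine fill)
intervals after a 75–120-day post-diagnosis start offset; radiotherapy as
weekday-only fraction runs per schedule (standard 25–28 at 2.0 Gy,
hypofractionated 15–16 at 2.66 Gy, APBI 10 at 3.4 Gy) with configurable
interruption (7–21-day gaps) and premature-truncation probabilities; all
patients diagnosed in a single fixed calendar year to keep fixtures stable.

Claims noise is two-level: a source captures an episode with its configured
sensitivity (this is the parameter the binary validation statistics
estimate), and captured episodes drop individual dates at a `date_dropout`
rate while always keeping at least one. False positives are injected per
(source, agent) among truly unexposed patients as short 1–2-date episodes,
mimicking billing artifacts, so one minus the false-positive rate is the
expected specificity. The abstraction side has its own sensitivity switch
(registry incompleteness) and optional multiplicative dose noise.

All randomness flows from one integer seed through three named substreams
(cohort, claims, abstraction) created as `default_rng([seed, stream])`;
dates are pure integer arithmetic, so outputs are identical across
platforms.

What the generator does **not** model — insurance churn, Medicare crossover,
realistic NDC package distributions, correlated multi-agent regimen
structure (AC-T etc.), twice-daily APBI billing — bounds what passing tests
show: the pipeline is exact on its own generative assumptions and recovers
configured operating points, but real claims feeds can violate those
assumptions in ways only a study against real abstraction can quantify.

## Reporting and suppression

The report pipeline emits per-agent quadrant/κ/metric tables, a per-source
union panel, chemotherapy and radiotherapy dose ICC tables, and quadrant
percentage summaries, with percentages at 1 decimal place. Counts below the
confidentiality threshold (default 11) are masked together with their
derived percentages; because a row of four quadrants plus its total would
expose any single masked cell, complement suppression (masking the smallest
remaining count) is on by default.

## Numerical and design choices

- Problem sizes: property suites use 200–1000 randomized instances; the
  end-to-end recovery experiment uses 5000 patients, which puts ~2
  Monte-Carlo SEs at about 1 percentage point on the estimated operating
  point.
- The assumed-creatinine default (0.8 mg/dL) reflects that claims lack labs;
  it is the single largest structural approximation in carboplatin dosing.
- Kappa's CI method and the n = 5 / n = 10 fraction-schedule doses were
  genuinely open choices; each is a documented config default rather than a
  constant.
- Degenerate inputs: empty tables and all-zero tables raise; zero
  denominators yield missing metrics; zero total variance yields ICC 0 with
  a warning; MSW = 0 with between-subject spread yields ICC 1 with CI (1, 1).

## Known limitations

Endocrine-therapy duration, regimen-name inference, neoadjuvant/adjuvant
intent, brachytherapy dose modelling beyond fraction counting, and
latent-class corrections for an imperfect gold standard are out of scope.
The bundled code map and regimen defaults must be reviewed before use on any
real claims feed.
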