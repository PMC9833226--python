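# fhscreen

Automated case-finding for **familial hypercholesterolemia (FH)** in
coronary-angiography registries.

FH is a common autosomal-dominant disorder of LDL-cholesterol metabolism.
Untreated carriers develop severe hypercholesterolemia and premature
atherosclerotic disease, yet the large majority are never diagnosed.
Cardiac catheterization laboratories see exactly the population where
case-finding pays off: patients with premature coronary artery disease
(CAD). `fhscreen` implements an automated screening tool for that
setting, aimed at clinical epidemiologists and registry teams. It:

1. **flags** patients with premature angiographic CAD — men < 55 y,
   women < 60 y, lumen-diameter stenosis > 50% — whose laboratory history
   before the CAD diagnosis ever showed total cholesterol ≥ 8 mmol/l or
   LDL-C ≥ 5 mmol/l;
2. **excludes** patients with an apparent secondary cause of the
   hypercholesterolemia (nephrotic syndrome / end-stage renal disease,
   uncontrolled diabetes with HbA1c > 70 mmol/mol, hypothyroidism with
   TSH > 10 mU/l, offending medication, cholestasis, or triglycerides
   > 10 mmol/l);
3. **scores** the survivors with the Dutch Lipid Clinic Network (DLCN)
   criteria — family history of early CAD (1 pt), personal premature CAD
   (2) and other premature vascular disease (1), tendon xanthomata (6) and
   arcus cornealis before 45 (4), an LDL-C band score (≥ 8.5 → 8,
   6.5–8.4 → 5, 5.0–6.4 → 3, 4.0–4.9 → 1 mmol/l), and a pathogenic
   LDLR/APOB/PCSK9 variant (8) — classifying totals as unlikely (< 3),
   possible (3–5), probable (6–8) or definite (≥ 9) FH;
4. **compares** the resulting groups (chi-square for categorical
   variables, Mann–Whitney U for continuous ones) and tabulates the
   stage-by-stage flow chart.

LDL-C is taken as recorded, or estimated from same-day lipid panels with
the Friedewald equation `LDL-C = TC − HDL-C − TG/2.2` (mmol/l, invalid
for TG > 4.5 mmol/l). The four Finnish LDLR founder mutations used by
regional genetic testing are catalogued in `fhscreen.founder_catalog()`.

Because registry data cannot be shipped, the package includes a synthetic
cohort generator: a seeded stochastic simulator with a latent FH state
per patient, and a deterministic 28,295-patient fixture that reproduces
the validation study's flow chart (see below).

## Worked example

```bash
fhscreen fixture --out fixture/
fhscreen screen --registry fixture/registry.csv --labs fixture/labs.csv --out report/
```

The second command prints the flow counts (also written to
`report/flow.json`):

```json
{
  "n_total": 28295,
  "n_premature_cad": 2678,
  "n_flagged": 211,
  "n_excluded": 49,
  "n_analyzed": 162,
  "n_unlikely": 0,
  "n_possible": 55,
  "n_probable": 103,
  "n_definite": 4,
  "n_probable_or_definite": 107,
  "n_genetically_tested": {"possible": 7, "probable_definite": 14},
  "n_pathogenic": 5,
  "n_cascade_referred": 2
}
```

Reading: of 28,295 angiography patients, 2,678 had premature CAD and 211
of them (0.7% of all patients, 8% of premature CAD) had a history of
severe hypercholesterolemia. Forty-nine (23%) had an apparent secondary
cause; of the 162 analyzed, 107 (51% of those flagged) met probable or
definite FH criteria — about 1 in 25 premature-CAD patients — yet only 14
of the 107 (13%) had ever been genetically tested, 5 of them (36%)
carrying a pathogenic variant. `report/patients.csv` holds the
per-patient decisions; feed it to

```bash
fhscreen stats --patients report/patients.csv --by dlcn --out table1.csv
```

to get the baseline-characteristics table, e.g. the hypertension row
`32 (58.2%)` vs `83 (77.6%)` with p = 0.010 and the diabetes row
`9 (16.4%)` vs `18 (16.8%)` with p = 0.941 (Pearson chi-square, no
continuity correction).

The same API is available in Python (`fhscreen.flowchart_fixture`,
`run_screen`, `decisions_frame`, `baseline_table`, ...), and
`fhscreen simulate --seed 42 --out sim/` draws a stochastic cohort with
a latent truth table for evaluating threshold choices via
`fhscreen.evaluate_screen`.

## Layout

- `fhscreen.cohort_model` — validated record types, CSV readers/writers,
  thresholds (`CohortConfig`), risk-factor derivation
- `fhscreen.lipid_engine` — Friedewald estimation, LDL resolution,
  lipid-history summarization, treatment-goal assessment
- `fhscreen.dlcn_engine` — DLCN item scoring, classification, founder
  catalog
- `fhscreen.screening_pipeline` — the staged screen and flow accounting
- `fhscreen.stats_engine` — chi-square, Mann–Whitney, baseline tables
- `fhscreen.synthetic_cohort` — stochastic simulator and deterministic
  fixture

See `docs/methods.md` for the modelling choices and their rationale.
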