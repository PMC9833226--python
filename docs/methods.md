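# Methods

## The screening model

`fhscreen` operationalizes a registry-based case-finding rule for
familial hypercholesterolemia (FH) among coronary-angiography patients.
The pipeline is a fixed cascade; a patient appears in exactly one branch
at every stage, so the stage counts always reconcile
(`n_flagged = n_excluded + n_analyzed`, and the analyzed split into the
four DLCN categories):

1. **Premature CAD.** Angiographic CAD is a lumen-diameter reduction
   strictly greater than 50% in any main coronary vessel; "premature"
   means age at the baseline angiography strictly below 55 y (men) or
   60 y (women). Age is exact fractional years (days / 365.25) — the
   source procedure does not state integer vs fractional age, and
   fractional age avoids a systematic half-year bias at the cutoffs.
   Patients with several angiographies are indexed by the first
   qualifying one.
2. **Lipid-history flag.** The highest pre-CAD total cholesterol and
   LDL-C are taken over the half-open window
   `[lab_window_start, cad_date)` (default window start 2000-01-01;
   measurements on the angiography day are *not* pre-CAD). The flag
   fires at TC ≥ 8 mmol/l or LDL-C ≥ 5 mmol/l. The comparison is
   inclusive by default — that is how the flagged patients were counted —
   with a `threshold_inclusive: false` switch for the strict reading.
3. **Secondary-cause exclusion.** Registry flags (nephrotic
   syndrome/ESRD, cholestasis, offending medication such as aripiprazole
   or anabolic steroids) and laboratory rules (any HbA1c > 70 mmol/mol,
   any TSH > 10 mU/l, any TG > 10 mmol/l) exclude a patient from FH
   analysis. All applicable reasons are reported, not only the first,
   because a referral decision should be auditable. Absent evidence
   never excludes: a patient whose TSH was never measured stays in.
   Fasting status is not recorded in the laboratory table, so every TG
   value is eligible for the TG rule.
4. **DLCN scoring.** Items and bands are the published ones (see
   README). Adaptations forced by registry reality: physical findings
   default to absent when not systematically recorded; the registry's
   single family-history flag maps to the 1-point family item (relative
   degree and relatives' lipid levels are not encoded, so the 2-point
   family sub-criteria are unreachable); unknown family history scores
   as absent and the count of unknowns is logged. The LDL-C used for
   scoring is the highest pre-CAD value *as recorded*, with no
   correction for lipid-lowering treatment (an optional pretreatment
   multiplier exists in the config and is off by default). A patient
   flagged only via TC with no pre-CAD LDL-C on file scores 0 LDL
   points.

**Genetic results and scoring.** The DLCN DNA item (8 points) is fed
only by *founder-panel* results recorded in the registry — the fact the
automated tool can see at screening time. Gene-panel (NGS) results are
follow-up investigations: they are counted in the genetic-testing flow
but do not retroactively reclassify a patient's screening score. This
distinction is what lets a cohort contain more pathogenic results than
definite-FH patients, exactly as a real screen-then-test workflow does.

## LDL-C resolution

A recorded LDL-C value is used verbatim; its method label defaults to
the assay era (Friedewald up to 2017-03-30, direct thereafter) when the
row does not say. Otherwise a complete same-day TC+HDL+TG triple yields
`TC − HDL − TG/2.2` (mmol/l), undefined for TG > 4.5 mmol/l; a negative
estimate is floored at 0 with a warning. The 2.2 divisor and the 4.5
validity limit are the standard mmol/l convention and are exposed in the
config. Same-day duplicates: the maximum participates in "highest
pre-CAD" hunts, the minimum in the post-CAD goal hunt, so duplicates can
only strengthen the evidence in the direction being sought. Values from
the two assay eras are mixed without harmonization, matching how the
registry history would be read. Post-CAD goal attainment
(LDL-C ≤ 1.8 mmol/l, inclusive) uses the single minimum post-CAD value
with no follow-up horizon.

## Statistics

- Categorical comparisons: Pearson chi-square on the contingency table,
  **no Yates continuity correction** — the dialect that reproduces the
  reference group comparisons (hypertension p = 0.010, diabetes
  p = 0.941 on the published cell counts).
- Continuous comparisons: two-sided Mann–Whitney U. Combined n ≤ 20
  without ties uses the exact permutation null; otherwise the normal
  approximation with tie and continuity corrections (at n = 8 + 8 the
  corrected approximation stays within 0.02 of exact enumeration; the
  uncorrected one does not).
- Quartiles: linear interpolation between order statistics (the common
  statistical-package default; no convention was mandated).
- p-values print to three decimals, `<0.001` below 0.0005.

Both tests are computed by `scipy.stats`; the test suite checks them
against independent oracles (closed-form Pearson sums, full enumeration
of rank assignments, and a 10⁵-resample permutation null).

## Synthetic data

**Deterministic fixture** (`flowchart_fixture`). 28,295 patients built
stratum by stratum, with no randomness, so the pipeline lands exactly on
the reference flow chart: 2,678 premature CAD, 211 flagged, 49 excluded
(15 hypertriglyceridemia, 10 uncontrolled diabetes, 8 hypothyroidism,
8 ESRD, 5 medication, 3 cholestasis — the published total, our split),
162 analyzed = 55 possible + 103 probable + 4 definite. Within the
analyzed groups the categorical marginals follow the reference baseline
table (sex 42/13 vs 75/32; family history 2 vs 101; hypertension 32 vs
83; diabetes 9 vs 18; smoking 18/11/26 vs 33/36/38; lipid-lowering
treatment 11+7 vs 29+12; post-CAD goal 12 vs 32). The four definite
patients arise three via LDL (≥ 8.5 band) and one via founder-panel DNA
(2 CAD + 1 family + 3 LDL + 8 DNA); 21 patients are tested (14
probable/definite, 7 possible) with 5 pathogenic results among the
tested probable/definite and 2 cascade referrals. Two deliberate
reconciliations: the one possible-FH patient the reference table places
in the 6.5–8.4 mmol/l LDL band is moved to ≤ 6.4 (that band forces ≥ 7
points, i.e. probable, under the scoring arithmetic), and the fifth
pathogenic result is realized as a gene-panel follow-up finding in a
probable patient (a founder-panel result would force ≥ 10 points, i.e. a
fifth definite). Individual lipid values are synthetic within their band
constraints — only counts and bands are faithful; continuous medians,
quartiles and their p-values are *not* reproduced and are not asserted
anywhere. Bulk strata (25,617 non-premature patients, 2,467 premature
below the lipid thresholds) are minimal records, mostly without
laboratory histories; small sub-strata carry below-threshold values and
pre-window (1999) high values to exercise the window logic. Angiography
dates span 2007–2017 and laboratory dates 2000–2018, the study window.

**Stochastic simulator** (`simulate_cohort`). A seeded generator with a
latent FH state per patient: ~62% male, angiography ages normal around
65.6/69.4 y (men/women), ≈ 9.5% premature, latent FH prevalence 2% by
default; FH-positive patients draw LDL-C from a log-normal with median
5.5 mmol/l (σ_log 0.18) vs 3.1 mmol/l (σ_log 0.28) otherwise, and report
family history with probability 0.80 vs 0.35. Lab panels (LDL-C, TC
consistent with an HDL/TG draw, TG) are scattered over the window, with
post-CAD LDL-C shrunk ×0.4–0.8 to mimic treatment. Defaults mirror the
validation cohort's headline descriptives; where no figure was reported
(σ of the log-normals, lab counts ~Poisson(3)+1) values were chosen once
as clinically plausible. What the simulator does *not* model: repeat
angiographies, assay drift between eras, correlated risk factors,
informative missingness of labs, pedigrees. Tests passing on synthetic
cohorts therefore demonstrate rule correctness and accounting
invariants, not real-world sensitivity of the screen.

`evaluate_screen` scores the tool's probable/definite call against the
latent state among premature-CAD patients (the target population);
sensitivity/PPV are reported as absent when their denominators are zero.

## Numerical and interface choices

- CSV dialect: comma-separated UTF-8, ISO-8601 dates, dot decimals,
  `true/false/unknown` tri-state for family history, semicolon-joined
  secondary-cause flags. Units are fixed per analyte (mmol/l lipids,
  mmol/mol HbA1c, mU/l TSH); any other unit is a row-level rejection,
  never a silent conversion. Bad rows are collected with row number and
  reason; only a missing column aborts a read. Note the HbA1c exclusion
  cutoff is on the IFCC mmol/mol scale (70 mmol/mol ≈ 8.6% NGSP).
- The registry carries one row per patient (first qualifying
  angiography) and includes a `cascade_referred` flag so the cascade
  count has a data home.
- All rule inequalities are strict exactly as defined (> 50% stenosis,
  > 140/90 mmHg, > 42 and > 70 mmol/mol, > 10 mU/l, > 10 mmol/l,
  > 25 kg/m²) except the flag thresholds (≥ by default, see above) and
  the LDL goal (≤ 1.8); boundary behaviour is pinned by tests.
- Analyzed patients scoring < 3 are kept in an `unlikely` bucket and
  surfaced as a data-quality anomaly in the log (a flagged premature-CAD
  patient with LDL ≥ 5 already scores ≥ 5, so the bucket should be
  empty).
- Problem sizes in the test suite: the fixture runs once per session
  (~5 s to generate, < 1 s to screen); the brute-force equivalence check
  draws 100 cohorts of 10–500 patients; the permutation oracle uses 10⁵
  resamples at n = 30 + 30.

## Known limitations

- The family-history item cannot award the DLCN 2-point sub-criteria,
  so totals are conservative for patients whose relatives' lipid data
  would qualify.
- Untreated-LDL correction is off by default; on-treatment maxima
  understate the true band for treated patients.
- The secondary-cause medication list is a registry flag, not a drug
  dictionary; chart review remains the source of that flag.
- The fixture reproduces counts, bands and categorical marginals, not
  individual-level lipid distributions; continuous-variable statistics
  on it are illustrative only.
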