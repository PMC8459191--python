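# Methods

This note documents the models, rules, and design choices behind the
package; it is the place to look before changing a default.

## The synthetic archive

The generator emulates a single-institution melanoma pathology archive.
Each patient is one independent draw from the following hierarchy:

1. **TIL grade** from the configured marginal (defaults 16.5% absent,
   73.0% nonbrisk, 10.4% brisk).
2. **Every other categorical feature conditional on TIL grade** through
   odds tilts: P(category | grade) ∝ marginal(category) ×
   tilt(grade, category). The default tilts are calibrated so the
   conditionals reproduce the study population's cross-tabulations (brisk
   tumors enriched among thin, young, non-ulcerated lesions). Setting all
   tilts to 1 makes features independent of TIL grade — the null
   configuration used in the calibration tests. Features are conditionally
   independent of each other given TIL grade; the real joint distribution
   beyond two-way margins is unknown, so this is a modeling choice, not a
   claim about real data.
3. **Continuous values within categories.** Age is uniform on 25–49 /
   50–69 / 70–89 within its stratum (putting the overall median near 61 y).
   Breslow thickness is a scaled Beta within the drawn T bin — T1:
   0.2+0.8·Beta(1.8,1.8), T2: 1+Beta(1,2), T3: 2+2·Beta(1,1.5), T4:
   4+4·Beta(1,2) — which lands the overall median near 1.2 mm with
   quartiles ≈ 0.7–2.5 mm. Mitotic rate is geometric (an overdispersed
   count) with mean 3.5/mm² (absent, nonbrisk) or 1.8/mm² (brisk), giving
   medians (IQRs) of 2 (1–6) and 1 (0–3).
4. **Reporting missingness**: each feature line is omitted with a
   per-feature probability matching the study's Unknown fractions
   (microsatellites 44.7%, vascular/lymphatic invasion 37.3%, Breslow
   3.3%, ulceration 1.8%, regression 1.0%, mitotic rate 0). An omitted
   line is the gold label "unknown" — the report-level truth is what the
   report says, not the latent biology.
5. **Survival**: exponential event time with hazard h₀·exp(lp), where lp
   sums per-term log-hazards over the *reported* profile (unknown levels
   carry their own coefficients, mirroring how the analysis model encodes
   them — this is what makes exact parameter recovery a meaningful test).
   Default coefficients are the natural logs of the study's adjusted
   hazard ratios; histologic regression and unknown-Breslow default to 0
   (the adjusted model reports no estimate for them). The baseline hazard
   h₀ = 0.0135/person-year was calibrated once so the whole-cohort 5-year
   KM estimate sits near 74% under the default censoring; death fraction
   comes out near 19–20%.
6. **Censoring**: diagnosis dates uniform over 2004-06-01..2019-12-31,
   administrative censoring at 2019-12-31, and loss to follow-up
   exponential at 0.152/year — chosen jointly so the reverse-KM median
   follow-up is ≈ 3.1 years (IQR ≈ 1.3–6.0). A death after loss to
   follow-up is invisible (no death date in the metadata), so the cohort
   builder's event count equals the generator's bookkeeping exactly.
7. **Eligibility**: 18.2% of patients are eligible; the rest fail as
   TIL-not-assessed (45%), no VGP (35%), no synoptic report (15%), or not
   primary invasive (5%). The failure-mode split is not documented for the
   real archive and was fixed arbitrarily. "Primary invasive" is a
   metadata flag rather than an extracted diagnosis line, since diagnosis
   classification is outside the seven extracted features. About 20% of
   patients receive 1–2 extra earlier reports (narrative biopsies, or —
   eligible patients only — superseded synoptic reports) to exercise the
   most-recent-synoptic rule; an ineligible patient never acquires
   eligibility through an extra report.

Randomness: one master seed; patient *i* uses
`SeedSequence(seed, spawn_key=(i,))`, so growing the corpus never
reshuffles earlier patients, and the fast cohort-level simulator shares
the per-patient substreams with the full text pipeline.

### Report rendering

Reports use a two-section institutional template ("Specimen(s)",
"Results") with one feature per line in the results block. Each line is
drawn from a variant table: a canonical phrasing, recoverable variants the
rule lexicon also covers ("present, at least brisk", "TILs: present
[brisk]", "No ulceration identified", …), and — in narrative prose only —
*hard* phrasings no lexicon head matches ("A dense lymphoid infiltrate
permeates the entire base of the lesion"). Synoptic blocks never use hard
phrasings: synoptic reporting is standardized by construction, while
narrative biopsies are where phrasing drifts. This is what bounds
extraction accuracy below 100% at nonzero variant intensity and makes
accuracy monotonically degrade as intensity rises, without ever
contaminating the canonical round-trip guarantee. `variant_intensity`
defaults to 0.25 with a 5% hard share on narrative TIL mentions, putting
report-level accuracy near 99.5%.

What the generator does **not** emulate: realistic clinical prose beyond
the rule classes, OCR noise, misspellings, inter-observer grading
variability, non-English text, or correlated missingness. Passing tests
therefore show the pipeline's logic is correct under its stated dialect —
not that the lexicons would transfer to another institution's reports
unedited (they are YAML data files precisely so they can be re-derived).

## Extraction rules

Segmentation matches known headers case-insensitively at line starts
(colon-terminated); text before the first header is a PREAMBLE segment;
spans are 0-based half-open and non-overlapping. Extraction is line-based:

- **TIL grade** value groups are ordered nonbrisk → brisk → absent so that
  "non-brisk" is never swallowed by the bare "brisk" pattern.
- **Negation scope** for tri-states: a negation cue on the same line
  within 5 tokens before the feature head, or an absent-cue after it;
  affirmation cues otherwise; no mention ⇒ unknown. One finding per line
  makes sentence-level scoping unnecessary.
- **Precedence** among multiple mentions: results/synoptic/addendum
  segments outrank narrative text; among those, the last mention wins
  (addenda supersede earlier text).
- **Numbers**: "at least X mm" floors report X; mitotic zero phrasings
  ("no mitotic figures identified", "<1/mm²") normalize to 0; a number
  without a per-area unit is unparseable and logged.
- **Synoptic detection**: an explicit synoptic marker, or ≥3 labeled
  feature lines in a results-type segment.

## Cohort rules

The selected report's date stands in for the date of diagnosis (the only
date guaranteed present). Same-date synoptic ties break lexicographically
by report id, logged. Years are days/365.25. A death dated after the
administrative censor date is treated as unobserved (censored at the admin
date). Exclusion reasons are checked in a fixed order (no synoptic → not
invasive → TIL not assessed → no VGP) so each patient is counted once and
the ledger conserves the archive total.

## Evaluation

Report-level "correctly extracted" means **all** features exact-match,
including unknown == unknown; a report with at least one gold feature and
all features matched counts toward precision/recall numerators. Numeric
matches tolerate 0.005 mm and 0.5/mm² so string-rendered decimals cannot
fail on formatting. Per-feature metrics use the same four counts
restricted to one feature. Empty corpora and zero denominators raise
rather than emitting NaN; F1 is defined 0 when P + R = 0.

## Survival statistics

lifelines provides the estimators; this package owns the encodings.
KM confidence bands use the log(−log) (exponential-Greenwood) transform,
which respects [0,1]; the variance reported per step is Greenwood's
formula computed from the event table. Cox ties use Efron's method. The
multivariable model drops rows with unknown Breslow thickness (as the
study did) and, by the same logic, unknown mitotic rate — the default
corpus produces none. Histologic regression is excluded from the
multivariable fit by default but `include_regression=True` restores it:
the source analysis lists it among adjustment variables yet reports no
adjusted estimate, so both variants are exposed rather than guessing.
Bonferroni multiplicity in subgroup analyses counts the strata actually
tested within one stratifier (strata with <2 TIL groups are skipped and
logged), not across stratifiers.

## Test selection in the descriptive table

"Sample size < 5" is read as *any observed cell count* below 5
(`rule="observed"`, the default); `rule="expected"` switches to
chi-square expected counts, since the original phrasing is ambiguous.
The r×c Fisher p is the probability-ordering two-sided value: exact
enumeration of all tables with the observed margins when the grand total
is ≤ 200, otherwise seeded Monte-Carlo with 100 000 tables (seed fixed and
logged). Chi-square is Pearson without continuity correction. Note the
exact and asymptotic p values only agree to ~0.02 once cell counts reach
the thousands; at desk scale the discreteness gap is real and the tests
assert it honestly.

## Problem sizes

The analysis scripts default to 4 000 archive patients (~750-patient
cohort), enough to exercise every stage while keeping a full run in tens
of seconds; effect-level conclusions are intentionally referred to the
parameter-recovery suite at n = 20 000, where every generating log-hazard
is recovered within 3 estimated SEs. Type-I-error calibration uses 1 000
null replicates of 180 patients with an elevated baseline hazard
(0.08/year) so each replicate carries enough events for the asymptotic
log-rank reference to be meaningful.

## Known limitations

- The rule lexicons are re-derived from the dialect description, not a
  reconstruction of any institution's production rule set.
- The generator's conditional-independence-given-TIL structure understates
  real feature correlations (e.g. thickness-ulceration beyond their shared
  TIL association).
- Exponential baselines have constant hazard; KM shapes are accordingly
  smooth and memoryless.
- The Fisher Monte-Carlo p has sampling error ~1/√B (~0.003 at the default
  100 000 tables).
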