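# melatil

Assessing the prognostic significance of tumor-infiltrating lymphocytes
(TILs) in primary cutaneous melanoma from semistructured pathology reports —
as a fully testable pipeline over a synthetic report archive with known
ground truth.

Real melanoma pathology archives are private, so every stage here runs
against a generator that emulates a single-institution archive: free-text
reports in an institutional dialect (predefined section headers, one
synoptic feature line per finding, lexical variants), patient metadata, and
survival outcomes drawn from a proportional-hazards model. Because the
generator's labels are known exactly, extraction quality, cohort rules, and
parameter recovery can all be verified end to end.

The package is for biostatisticians and clinical-NLP engineers who want a
reference implementation of this study design: rule-based information
extraction feeding a survival analysis, with the evaluation harness built
in.

## What it implements

- **Rule-based extraction** of seven pathologic characteristics from report
  text: TIL grade (Clark tiers *absent* / *present, nonbrisk* / *present,
  brisk*), Breslow thickness (mm), mitotic rate (per mm²), ulceration,
  histologic regression, microsatellites, and vascular/lymphatic invasion —
  plus vertical-growth-phase (VGP) and synoptic-format detection. Rules are
  editable YAML lexicons; every non-unknown extraction cites the character
  span it came from.
- **Cohort construction**: per patient, the most recent synoptic report is
  selected; patients enter the cohort when it documents a primary invasive
  melanoma with TIL grade assessed and VGP present. Overall survival (OS)
  runs from diagnosis to death from any cause, censored at last follow-up
  or 2019-12-31. T category follows the AJCC Breslow cut points
  (T1 ≤ 1.0 < T2 ≤ 2.0 < T3 ≤ 4.0 < T4).
- **Extraction evaluation** with the four report-level metrics:
  accuracy = correct/evaluated, precision = correct/identified,
  recall = correct/with-results, F1 = 2PR/(P+R).
- **Survival statistics**: Kaplan-Meier S(t) with Greenwood variance and
  log(−log) 95% bands, k-sample log-rank, reverse-KM median follow-up, and
  univariable/multivariable Cox models (Efron ties) with the study
  encodings — age strata (<50 ref), sex (female ref), TIL grade (absent
  ref), Breslow per mm, mitotic rate per unit, tri-states with explicit
  Unknown levels.
- **Descriptive table** by TIL grade with the test-selection rule:
  Kruskal-Wallis for continuous variables; chi-square for categorical
  variables, switching to the Fisher exact test when any observed cell
  count is below 5 (exact enumeration for small r×c tables, seeded
  Monte-Carlo otherwise).
- **Synthetic generator** calibrated to the study population: TIL marginals
  16.5/73.0/10.4%, odds tilts linking TIL grade to age and T category,
  adjusted hazard ratios as generating coefficients (e.g. brisk 0.63,
  ≥70 y 3.37, male 1.50, ulceration 2.14), exponential baseline, uniform
  accrual 2004–2019 with loss to follow-up tuned so the reverse-KM median
  follow-up sits near 3.1 years.

## Worked example

The numbered scripts under `analysis/` run the study at a scaled-down
archive size (4 000 patients, ~5 200 reports):

```bash
python analysis/01_generate_corpus.py      # archive -> scratch/corpus
python analysis/02_extract_and_evaluate.py # rule extraction + scoring
python analysis/03_build_cohort.py         # inclusion rules + OS
python analysis/04_table_one.py            # descriptives by TIL grade
python analysis/05_survival_analysis.py    # KM / log-rank / Cox
```

which prints, stage by stage:

```
wrote 5243 reports for 4000 patients to scratch/corpus; 748 patients (18.7%) carry an eligible synoptic report
scored 5243 reports: accuracy 0.9964, precision 0.9964, recall 0.9964, F1 0.9964
cohort: 748 of 4000 patients, 146 deaths; exclusions {'til_not_assessed': 1464, 'no_vertical_growth_phase': 1157, 'no_synoptic_report': 474, 'not_primary_invasive': 157}
5-year OS 74.0% (95% CI 69.5-78.0%); median follow-up 3.18 y; log-rank across TIL grades chi2=1.48 p=0.48; adjusted HR brisk vs absent 0.94 (0.49-1.80)
```

Reading these: the extractor recovers 99.6% of reports exactly (its misses
are free-prose TIL phrasings in narrative biopsies); 18.7% of archive
patients survive the inclusion funnel; the cohort's 5-year OS is ~74% with
a median follow-up near 3 years. At 748 patients the TIL effect is not
resolvable — the brisk hazard ratio's confidence interval spans 1 — which
is exactly why the parameter-recovery suite refits the model at n = 20 000,
where every generating log-hazard is recovered within 3 standard errors
(`tests/test_acceptance.py`).

The same stages are available as a CLI (`melatil generate / extract /
evaluate / cohort / table-one / analyze / run`); `melatil run` executes
them in order and writes a manifest of artifact digests so a rerun with
the same seed is verifiably identical.

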