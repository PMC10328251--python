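# cdeaudit

**Common-data-element audit of OMOP CDM study data.**

Large cohort studies increasingly store both research data (survey answers
collected on case report forms, CRFs) and imported electronic-health-record
(EHR) data in the OMOP Common Data Model. A recurring question for study
designers and clinical research informaticists is *how standardized is the
data actually collected*: which questions are **common data elements**
(CDEs) drawn from established terminologies such as LOINC or SNOMED CT, and
which are **unique data elements** (UDEs) minted in a study-custom
vocabulary (e.g. the Participant Provided Information, "PPI", terminology of
the All of Us program)?

`cdeaudit` answers that question reproducibly from four OMOP CDM v5.x tables
(CONCEPT, CONCEPT_RELATIONSHIP, MEASUREMENT, OBSERVATION, plus optional
`*_EXT` side tables carrying per-row `src_id` source labels). It builds:

- a **data-element dictionary** — per element: event count, distinct
  participants, percent coverage, origin class (CDE iff
  `vocabulary_id ∉ custom set`, default `{PPI, AoU_General}`), data type
  (numeric iff strictly more than half of its rows carry
  `value_as_number`), initiative provenance (PhenX, PROMIS, ... joined via
  the LOINC code), and CRF assignment by bounded upward traversal of the
  concept hierarchy (element → topic → module);
- a **permissible-value dictionary** — every (element, value) combination
  over categorical elements, with uncoded rows kept under an explicit NONE
  sentinel; per-value reuse across elements; answer-avoidance flags
  ('PMI: Skip', 'I prefer not to answer'); per-terminology value profiles;
  and element/value terminology concordance;
- a **CRF/EHR crossover analysis** — elements with rows from both the CRF
  source (`src_id ∈ {PPI/PM, PM/PPI}`) and EHR sites, with per-element
  `pct_from_crf = n_CRF / (n_CRF + n_EHR) × 100`, and the two-axis
  origin × ingestion classification of CDEs;
- **small-cell suppression** — no exported aggregate row may represent
  fewer than 20 distinct participants (configurable), enforced and
  accounted for on every rendered report.

Because real enclave data cannot leave its enclave, the package ships two
synthetic data sources: a seeded **generator** that plants exact category
counts (vocabulary mixture, numeric fraction, skip-enabled fraction,
crossover fraction, CRF layout) and emits a ground-truth manifest for
recovery testing, and a deterministic **reference study** whose aggregate
profile reproduces the published marginals of the All of Us registered-tier
CRF audit (1 033 elements, 164 CDEs, 932 values, 4 592 element-value
combinations, 64 crossover elements, ...).

## Worked example

```python
import cdeaudit as ca

bundle, truth = ca.generate_study(ca.GeneratorConfig(seed=42, n_elements=25, n_participants=120))
result = ca.profile_study(bundle)
s = result.summary
print(f"elements: {s.total_elements}  (CDE {s.by_origin.get('CDE',0)}, UDE {s.by_origin.get('UDE',0)})")
print(f"element-value combinations: {len(result.pairs)}, distinct values: {len(result.values)}")
print(f"skip-enabled elements: {result.avoidance.n_skip_enabled} ({result.avoidance.pct_skip_enabled}%)")
print(f"crossover elements: {len(result.crossover)}")
print(s.by_crf.to_string(index=False))
```

prints

```
elements: 25  (CDE 4, UDE 21)
element-value combinations: 117, distinct values: 86
skip-enabled elements: 18 (72.0%)
crossover elements: 2
            crf  elements  pct_of_total  udes  cdes
No CRF Declared         8          32.0     8     0
       Module 1         4          16.0     4     0
       Module 2         4          16.0     3     1
       Module 3         4          16.0     3     1
       Module 4         3          12.0     1     2
       Module 5         2           8.0     2     0
```

25 synthetic elements were generated with the default AoU-like composition
(~84% custom PPI concepts, 4% numeric, 72% skip-enabled); the audit
recovered every planted count exactly (`truth.globals` carries the
manifest). "No CRF Declared" collects elements with no hierarchy link —
typically research-visit measurements such as vital signs.

The same pipeline is available from the shell:

```bash
cdeaudit simulate --seed 42 --out study/     # synthetic bundle + ground truth
cdeaudit report --in study/ --out reports/   # suppressed, deterministic reports
cdeaudit profile --concepts concept.csv --observations observation.csv ... --out reports/
cdeaudit fixture --out ref/                  # the reference (published-marginals) bundle
```

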