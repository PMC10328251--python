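# Methods

## The audit model

The package treats a study's OMOP CDM extract as a closed relational world:
the CONCEPT table is the vocabulary layer, CONCEPT_RELATIONSHIP is a
directed multigraph over concepts, and MEASUREMENT/OBSERVATION rows are
unified into *clinical events* `(event_id, person_id, element_concept_id,
domain, value_as_number, value_as_concept_id, src_id)`. Every analysis is a
deterministic aggregation over this world; nothing is estimated or fitted.

**Element scope.** The audit reports on *CRF elements*: element concepts
with at least one row attributed to the research/CRF source. Once an
element is in scope, all of its rows (including EHR-imported ones) count in
its usage volume — which is what makes the crossover percentages meaningful.

**Origin classification.** CDE iff the element's `vocabulary_id` is not in
the configured custom set (`{PPI, AoU_General}` by default). This is a pure
vocabulary-membership rule; it deliberately classifies as UDEs those survey
questions that were adapted from existing instruments but formalized as
custom concepts, because nothing in the data distinguishes them.

**Data type.** An element is numeric iff strictly more than half of its
rows have a `value_as_number`. The strictness matters: at exactly half the
element is categorical. The rule is applied per element over all of its
rows, so site-to-site variation in recording practice is averaged out.

**CRF assignment.** Survey hierarchies in the OMOP vocabulary layer link a
question to a topic and a topic to a module (the CRF). The assignment walks
edges whose `relationship_id` is in the configured list (default
`["Has PPI parent code", "Is a"]` — the study whose data this audit was
designed for publishes its hierarchy under PPI parent links, but the list
is a config knob because deployments differ) breadth-first upward from the
element, bounded at depth 5. The first concept of class `Topic` is the
topic; the nearest concept of class `Module` is the CRF. Ties at the same
depth resolve to the lexicographically smallest module name and are flagged
ambiguous. A cycle among the followed edges raises an error rather than
silently truncating. Elements that reach no module are reported under
`No CRF Declared`.

**Permissible values.** Value identity is the `value_as_concept_id`, never
the display name (the same name can exist in two terminologies). Rows with
id 0 or missing are normalized to an explicit NONE sentinel (concept 0,
vocabulary "None") that participates in pair counts and the terminology
profile but never in avoidance detection. Numeric elements are excluded
from the value dictionary; coded rows they carry land in a diagnostics
table. `pct_of_element` uses the element's total categorical rows —
including avoidance and NONE rows — as denominator.

**Standardized values.** A value is standardized iff its vocabulary is not
in the custom set. Under this rule the NONE sentinel counts as
standardized; that convention is what makes the published value-level
marginals (575 of 932 standardized) internally consistent, and it is the
rule the package applies uniformly.

**Answer avoidance.** Skip-enabled: the element's observed value set
contains the skip concept (903096). Avoidance-enabled: it intersects the
wider avoidance set ({903096, 1177221}). Detection is over *observed*
pairs; a value that is permitted but never chosen is invisible to the
audit, which is the honest reading of usage data.

**Crossover and axes.** A row is CRF iff `src_id` is in the configured CRF
label set (both spellings `PPI/PM` and `PM/PPI` by default; any other label
is an EHR site; a missing label is an error in strict mode, EHR in lenient
mode). A crossover element has ≥1 row from each side; identity is exact
concept-id equality, with no semantic mapping. The two-axis view then
splits CDEs into O1-healthcare (present in routine healthcare — the
crossover list, or an explicitly supplied healthcare-element universe) vs
O2-research, and T1-ingested vs T2-non-ingested; with an element universe
drawn from OMOP-ingested terminologies the O2/T2 cell is structurally
empty but still reported. UDEs sit outside the classification. The O1 row
total (healthcare elements beyond CRF scope) is only reported when a
universe is supplied, since it cannot be derived from CRF data alone.

**Suppression.** Exported aggregate rows must represent ≥ 20 distinct
participants. Suppression acts on distinct-participant counts, is applied
per row of every table that has a participant dimension (most
conservative), and always returns an accounting object with
`rows_out + rows_suppressed = rows_in`. Tables with no participant
dimension are exempt but flagged in the report metadata. A table that lacks
the participant column where one is expected is a hard error — suppression
never silently passes.

## Rounding

Printed percentages use round-half-away-from-zero (not banker's rounding):
1 decimal in narrative figures, 2 decimals in table figures; both
configurable. Sort orders in reports are fixed (descending event count,
ties by ascending concept id), so re-rendering identical inputs is
byte-identical.

## The synthetic generator

`generate_study` emulates the *structure* of a survey-plus-EHR cohort in
OMOP form, not its clinical content. Category counts are planted by exact
largest-remainder allocation of the configured proportions — never sampled
— so recovery tests are exact rather than statistical; the seed only
permutes identifiers and drives per-row answer draws, and the ground-truth
manifest is recorded from the rows actually emitted. Persons are assigned
to each element as a contiguous block, which makes participant counts
controllable at the cost of realism.

Defaults mirror the composition of a large national cohort's CRF data:
vocabulary mixture LOINC 0.100 / SNOMED 0.058 / UCUM 0.001 / PPI 0.841,
numeric fraction 0.04, 2–8 values per element, skip-enabled fraction 0.72,
per-row avoidance use rate 0.02, crossover fraction 0.06 with EHR row share
0.3, initiative fraction 0.84 of LOINC elements, 5 modules × 2 topics, 30%
of elements outside any CRF, 30 rows per element over 500 participants.

What the generator does **not** model: realistic clinical value
distributions, longitudinal visits, site heterogeneity, EHR-only elements,
missingness mechanisms, or correlations between answers. Passing recovery
tests therefore demonstrates the *accounting correctness* of the pipeline —
that every classification and count is computed as specified — not its
behavior under messy real-world coding practices.

## The reference study

`make_reference_study` builds a seedless, deterministic bundle whose
aggregate profile reproduces the published marginals of the All of Us
registered-tier CRF audit exactly: the element dictionary
(1 033 elements; 103 LOINC / 60 SNOMED / 1 UCUM / 869 PPI; 41 numeric;
per-CRF counts down to 2 EHRConsent PII elements), initiatives (87 CDEs
over 15 initiatives, 17 PhenX), the value catalogue (932 distinct values,
4 592 combinations, 672 single-element values, 748 skip-enabled / 801
avoidance-enabled elements), the exact per-value counts of the
health-insurance (931 119 rows) and alcohol-frequency (402 030 rows)
elements, and 64 CDE crossover elements (alcohol 99.1% CRF-sourced, heart
rate 94.1% EHR-sourced). Everything not pinned by a published number —
names, identifiers, the small per-pair counts of generic elements — is
synthetic and chosen so that every exported cell clears the 20-participant
threshold. Two published figures could not be honored verbatim because
they are internally inconsistent: the per-CRF UDE/CDE split of the
"No CRF Declared" row is reconciled to 165/141 so that the global CDE/UDE
totals (164/869) hold, and the alcohol 'I prefer not to answer' share
prints as 2.5% (9 940/402 030), not 2.4%.

Building the bundle materializes ~1.4M event rows (the two exact-count
elements dominate); profiling it takes a few seconds on one CPU.

## Problem sizes and numerical choices

- Ground-truth recovery is exercised over 50 seeded configurations of
  40–80 elements and 150–250 participants spanning five vocabulary
  mixtures, numeric fractions 0–0.15, skip fractions 0.4–0.8 and crossover
  fractions 0–0.2; recovery is asserted exactly, with zero tolerance.
- Percentage-closure tolerance: per element, Σ pct_of_element must lie
  within ±0.1 × (number of values) of 100 — the worst case of half-up
  rounding at 1 decimal.
- Degenerate inputs: empty event stores profile to empty dictionaries;
  an element with zero rows cannot exist (error); empty aggregate tables
  suppress to empty outputs with balanced accounting.

## Known limitations

- CRF assignment depends on a configurable relationship list; a deployment
  using different hierarchy links must set `crf_relationship_ids`.
- The audit trusts element concept ids as recorded; it performs no
  source-value re-mapping or semantic validation of EHR coding.
- Avoidance detection sees only observed values, so a never-used skip
  option is not counted as "available".
- All tables are held in memory as pandas frames; extracts far beyond ~10M
  rows would call for a chunked or database-backed backend.
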