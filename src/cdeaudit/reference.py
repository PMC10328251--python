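"""Synthetic reconstruction of the All of Us registered-tier CRF profile.

The real study data (registered tier, release R2021Q3R2) is access-restricted
and cannot ship; this module builds a fully synthetic OMOP bundle whose
*aggregate* profile reproduces the published marginals of that release
exactly, so the whole pipeline can be exercised end to end against known
printed numbers:

* 1 033 CRF elements: 103 LOINC, 60 SNOMED, 1 UCUM, 869 PPI (164 CDEs);
* 41 numeric / 992 categorical elements;
* per-CRF element counts (461 Personal Medical History, 306 with no CRF,
  118 COPE, ... down to 2 EHRConsent PII);
* 87 initiative CDEs across 15 initiatives (17 PhenX, 15 PROMIS, ...);
* 932 distinct permissible values (357 SNOMED, 194 LOINC, 344 PPI,
  13 AoU_General, 11 ICD9CM, 9 ICD10CM, 3 UCUM, 1 None) and 4 592
  element-value combinations, 672 values used by a single element;
* 748 skip-enabled elements, 63 with 'I prefer not to answer', 801 with
  either;
* exact printed per-value counts for the health-insurance (931 119 rows)
  and alcohol-frequency (402 030 rows) elements;
* 64 CDEs with rows from both the CRF source and EHR sites.

Everything else about the bundle (names, identifiers, row-level person
assignment, the small per-pair counts of the generic elements) is synthetic
and deliberately unremarkable.  The builder is seedless and deterministic:
two calls yield identical frames.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd

from .bundle import StudyBundle
from .config import NONE_VALUE_ID

TOTAL_PARTICIPANTS = 329_070

SKIP = 903096
PREFER_NOT = 1177221
YES_L = 45877994
NO_L = 45878245
NO_S = 4188540
DONT_KNOW_L = 45877986

# (crf, n_loinc_cde, n_snomed_cde, n_ucum_cde, n_ude) -- specials counted in
_CRF_LAYOUT = [
    ("Personal Medical History", 0, 0, 0, 461),
    ("No CRF Declared", 81, 60, 0, 165),
    ("COVID-19 Participant Experience (COPE)", 0, 0, 0, 118),
    ("Healthcare Access & Utilization", 0, 0, 0, 57),
    ("GROR", 0, 0, 0, 26),
    ("The Basics", 12, 0, 0, 9),
    ("Lifestyle", 9, 0, 1, 4),
    ("Primary Consent Update", 0, 0, 0, 10),
    ("Overall Health", 1, 0, 0, 8),
    ("Family History", 0, 0, 0, 6),
    ("Consent PII", 0, 0, 0, 3),
    ("EHRConsent PII", 0, 0, 0, 2),
]

_INITIATIVE_COUNTS = [
    ("PhenX", 17), ("PROMIS", 15), ("Reported.PHQ", 14),
    ("Perceived Stress Scale-10", 10), ("MOS Social Support Survey", 9),
    ("HHS.ACA Section 4302", 6), ("SAMHSA", 5), ("IPAQ", 3),
    ("UCLA Loneliness Scale v3", 2),
    ("AUDADIS-IV", 1), ("AUDIT-C", 1), ("BRFSS", 1), ("NHIS", 1), ("PATH", 1), ("NHANES", 1),
]

_INSURANCE_VALUES = [  # concept name, vocabulary, rows
    ("Yes", "LOINC", 554_459, YES_L),
    ("Insurance through a current or former employer or union", "PPI", 136_606, None),
    ("Medicare, for people 65 and older or people with certain disabilities", "PPI", 110_455, None),
    ("Insurance purchased directly from an insurance company", "PPI", 42_737, None),
    ("No", "SNOMED", 27_820, NO_S),
    ("Medicaid or other government-assistance plan", "PPI", 21_589, None),
    ("Any other type of health insurance or health coverage plan", "PPI", 12_501, None),
    ("Veterans Affairs (VA)", "PPI", 11_955, None),
    ("PMI: Skip", "PPI", 9_429, SKIP),
    ("Don't know", "LOINC", 3_270, DONT_KNOW_L),
    ("None", "None", 298, NONE_VALUE_ID),  # remainder rows carry no coded value
]

_ALCOHOL_VALUES = [
    ("Monthly or less", "LOINC", 117_229),
    ("Never", "LOINC", 81_020),
    ("2-4 times a month", "LOINC", 78_459),
    ("2-3 times a week", "LOINC", 58_297),
    ("4 or more times a week", "LOINC", 57_085),
    ("I prefer not to answer", "LOINC", 9_940),
]
ALCOHOL_EHR_ROWS = 3_779   # 99.06% of the 402 030 rows remain CRF-sourced

# generic value pool quotas: vocab -> (n_multi_element, n_single_element)
_GENERIC_VALUE_QUOTAS = [
    ("SNOMED", 150, 206),
    ("PPI", 50, 284),
    ("LOINC", 37, 142),
    ("ICD10CM", 5, 4),
    ("ICD9CM", 6, 5),
    ("UCUM", 2, 1),
    ("AoU_General", 3, 10),
]


def _build_elements() -> pd.DataFrame:
    """The 1 033 element concepts with vocabulary, CRF and data type."""
    rows = []
    next_id = itertools.count(50_000_000)
    next_code = itertools.count(1)

    def add(name, vocab, crf, numeric=False, concept_id=None, code=None, special=None):
        rows.append({
            "concept_id": concept_id if concept_id is not None else next(next_id),
            "concept_name": name,
            "vocabulary_id": vocab,
            "concept_code": code if code is not None else f"R{next(next_code)}-{vocab[:1]}",
            "numeric": numeric,
            "crf": crf,
            "special": special,
        })

    # special elements with exact printed value counts
    add("Are you covered by health insurance or some other kind of health care plan [PhenX]",
        "LOINC", "The Basics", concept_id=40766240, code="63513-6", special="insurance")
    add("Marital status", "LOINC", "The Basics", concept_id=3046344, code="45404-1", special="marital")
    add("How often do you have a drink containing alcohol", "LOINC", "Lifestyle",
        concept_id=40771103, code="68518-0", special="alcohol")
    add("Home Own: Current Home Own", "PPI", "The Basics", concept_id=1585370,
        code="HomeOwn_CurrentHomeOwn", special="homeown")

    # named no-CRF vitals (numeric, research visit)
    add("Heart rate", "LOINC", "No CRF Declared", numeric=True, concept_id=3027018, code="8867-4")
    add("Body weight", "LOINC", "No CRF Declared", numeric=True, concept_id=3025315, code="29463-7")
    add("Body mass index (BMI) [Ratio]", "LOINC", "No CRF Declared", numeric=True,
        concept_id=3038553, code="39156-5")
    add("Diastolic blood pressure", "LOINC", "No CRF Declared", numeric=True,
        concept_id=3012888, code="8462-4")
    for i in range(36):
        add(f"Research visit measurement {i + 1}", "LOINC", "No CRF Declared", numeric=True)
    # named no-CRF SNOMED history elements
    add("History of clinical finding in subject", "SNOMED", "No CRF Declared",
        concept_id=4214956, code="417662000")
    add("Family history of sickle cell anemia", "SNOMED", "No CRF Declared",
        concept_id=4050803, code="160320002")
    add("Family history of breast cancer", "SNOMED", "No CRF Declared",
        concept_id=4179963, code="429740004")
    add("Days per week?", "UCUM", "Lifestyle", numeric=True, concept_id=8621, code="{d}/wk")

    placed = {}
    for r in rows:
        key = (r["crf"], r["vocabulary_id"], bool(r["numeric"]))
        placed[key] = placed.get(key, 0) + 1
    for crf, n_loinc, n_snomed, n_ucum, n_ude in _CRF_LAYOUT:
        n_num_loinc = 40 if crf == "No CRF Declared" else 0
        done_num = placed.get((crf, "LOINC", True), 0)
        done_cat = placed.get((crf, "LOINC", False), 0)
        for i in range(n_num_loinc - done_num):
            add(f"{crf} numeric element {i + 1}", "LOINC", crf, numeric=True)
        for i in range(n_loinc - n_num_loinc - done_cat):
            add(f"{crf} question {i + 1}", "LOINC", crf)
        for i in range(n_snomed - placed.get((crf, "SNOMED", False), 0)):
            add(f"{crf} history finding {i + 1}", "SNOMED", crf)
        for i in range(n_ucum - placed.get((crf, "UCUM", True), 0)):
            add(f"{crf} unit question {i + 1}", "UCUM", crf, numeric=True)
        for i in range(n_ude - placed.get((crf, "PPI", False), 0)):
            add(f"{crf} custom question {i + 1}", "PPI", crf)
    df = pd.DataFrame(rows)
    assert len(df) == 1033 and df["concept_id"].is_unique
    assert df["vocabulary_id"].value_counts().to_dict() == {"PPI": 869, "LOINC": 103, "SNOMED": 60, "UCUM": 1}
    assert int(df["numeric"].sum()) == 41
    return df


def _assign_initiatives(elements: pd.DataFrame) -> pd.DataFrame:
    """87 LOINC CDEs carry an initiative; the insurance element is PhenX."""
    labels = [lab for lab, k in _INITIATIVE_COUNTS for _ in range(k)]
    named_vitals = {3027018, 3025315, 3038553, 3012888}
    pool = elements[(elements["vocabulary_id"] == "LOINC")
                    & ~elements["concept_id"].isin(named_vitals)].copy()
    pool = pd.concat([pool[pool["special"] == "insurance"],
                      pool[pool["special"] != "insurance"]])
    chosen = pool.head(len(labels))
    assert len(chosen) == 87
    return pd.DataFrame({"loinc_code": chosen["concept_code"].to_numpy(), "initiative": labels})


def _build_value_catalogue_and_pairs(elements: pd.DataFrame):
    """Plant the 932-value catalogue and the 4 592 element-value pairs.

    Generic categorical elements are indexed G[0..987] in construction
    order; index ranges below realize the published multi-element value
    counts (748 skip-enabled, 63 prefer-not with overlap 10, 241 'Yes',
    349 LOINC 'No', 68 elements with uncoded rows, 10 'Don't know',
    20 SNOMED 'No') and the 672/260 single/multi split.
    """
    cat = elements[~elements["numeric"]]
    generic = cat[cat["special"].isna()]["concept_id"].to_numpy()
    assert len(generic) == 988
    spec_ids = {s: int(cat.loc[cat["special"] == s, "concept_id"].iloc[0])
                for s in ("insurance", "marital", "alcohol", "homeown")}

    value_concepts: list[dict] = []

    def add_value(cid, name, vocab):
        if cid != NONE_VALUE_ID:
            value_concepts.append({"concept_id": cid, "concept_name": name, "vocabulary_id": vocab,
                                   "concept_code": f"V{cid}", "concept_class_id": "Answer",
                                   "standard_concept": "S"})

    add_value(SKIP, "PMI: Skip", "PPI")
    add_value(PREFER_NOT, "I prefer not to answer", "LOINC")
    add_value(YES_L, "Yes", "LOINC")
    add_value(NO_L, "No", "LOINC")
    add_value(DONT_KNOW_L, "Don't know", "LOINC")
    add_value(NO_S, "No", "SNOMED")

    pairs: list[tuple[int, int, int]] = []  # element_id, value_id, rows

    def cnt(g_idx, salt=0):
        return 20 + (g_idx + salt) % 5

    for g_idx in range(746):                       # PMI: Skip on 746 generics
        pairs.append((generic[g_idx], SKIP, cnt(g_idx)))
    for g_idx in list(range(737, 746)) + list(range(746, 797)):   # prefer-not on 60
        pairs.append((generic[g_idx], PREFER_NOT, cnt(g_idx, 1)))
    for g_idx in range(240):                       # Yes on 240
        pairs.append((generic[g_idx], YES_L, cnt(g_idx, 2)))
    for g_idx in range(349):                       # LOINC No on 349
        pairs.append((generic[g_idx], NO_L, cnt(g_idx, 3)))
    for g_idx in range(921, 988):                  # uncoded rows on 67
        pairs.append((generic[g_idx], NONE_VALUE_ID, cnt(g_idx, 4)))
    for g_idx in range(240, 249):                  # Don't know on 9
        pairs.append((generic[g_idx], DONT_KNOW_L, cnt(g_idx, 5)))
    for g_idx in range(349, 368):                  # SNOMED No on 19
        pairs.append((generic[g_idx], NO_S, cnt(g_idx, 6)))

    # generic pool: 253 multi-element values first, then 652 single-element
    pool_vocabs = ([v for v, m, _s in _GENERIC_VALUE_QUOTAS for _ in range(m)]
                   + [v for v, _m, s in _GENERIC_VALUE_QUOTAS for _ in range(s)])
    assert len(pool_vocabs) == 905
    for j, vocab in enumerate(pool_vocabs):
        vid = 60_000_000 + j
        add_value(vid, f"Reference value {j + 1}", vocab)
        first = 987 - j
        pairs.append((generic[first], vid, cnt(first, j)))
        if j < 253:                                # extra placements for multi values
            n_extra = 9 if j < 144 else 8
            for m in range(1, n_extra + 1):
                e = (first + m) % 988
                pairs.append((generic[e], vid, cnt(e, j)))

    # special elements: exact printed counts
    next_special = itertools.count(61_000_000)
    for name, vocab, rows, *fixed in _INSURANCE_VALUES:
        vid = fixed[0] if fixed and fixed[0] is not None else next(next_special)
        if vid not in (SKIP, YES_L, NO_S, DONT_KNOW_L, NONE_VALUE_ID):
            add_value(vid, name, vocab)
        pairs.append((spec_ids["insurance"], vid, rows))
    for name, vocab, rows in _ALCOHOL_VALUES:
        vid = PREFER_NOT if name == "I prefer not to answer" else next(next_special)
        if vid != PREFER_NOT:
            add_value(vid, name, vocab)
        pairs.append((spec_ids["alcohol"], vid, rows))
    for name, rows in (("Current Home Own: Own", 145), ("Current Home Own: Rent", 133),
                       ("Current Home Own: Other Arrangement", 35)):
        vid = next(next_special)
        add_value(vid, name, "PPI")
        pairs.append((spec_ids["homeown"], vid, rows))
    pairs.append((spec_ids["homeown"], PREFER_NOT, 29))
    for name, rows, cid in (("Married", 41, 45876756), ("Never married", 26, 45881671),
                            ("Divorced", 24, 45883375), ("Living with partner", 22, 45883710),
                            ("Widowed", 21, 45883711), ("Separated", 20, 45884459)):
        add_value(cid, name, "LOINC")
        pairs.append((spec_ids["marital"], cid, rows))
    pairs.append((spec_ids["marital"], PREFER_NOT, 20))
    pairs.append((spec_ids["marital"], SKIP, 20))

    pair_df = pd.DataFrame(pairs, columns=["element_concept_id", "value_concept_id", "rows"])
    assert len(pair_df) == 4592
    assert not pair_df.duplicated(["element_concept_id", "value_concept_id"]).any()
    distinct = pair_df["value_concept_id"].nunique()
    assert distinct == 932
    single = (pair_df.groupby("value_concept_id")["element_concept_id"].nunique() == 1).sum()
    assert int(single) == 672
    return pd.DataFrame(value_concepts), pair_df, spec_ids


def _crossover_plan(elements: pd.DataFrame, spec_ids: dict) -> dict[int, int]:
    """element_id -> number of EHR rows; 64 CDEs get both-source rows."""
    plan: dict[int, int] = {3027018: 400}          # heart rate: mostly EHR
    numeric_loinc = elements[elements["numeric"] & (elements["vocabulary_id"] == "LOINC")]
    for cid in numeric_loinc["concept_id"]:
        plan.setdefault(int(cid), 15)
    plan[spec_ids["alcohol"]] = ALCOHOL_EHR_ROWS
    snomed = elements[elements["vocabulary_id"] == "SNOMED"]["concept_id"].to_numpy()
    for cid in snomed[:23]:
        plan[int(cid)] = -1                         # sentinel: 30% of the element's rows
    assert len(plan) == 64
    return plan


def make_reference_study() -> StudyBundle:
    """Build the deterministic reference bundle (synthetic throughout)."""
    elements = _build_elements()
    initiatives = _assign_initiatives(elements)
    value_concepts, pair_df, spec_ids = _build_value_catalogue_and_pairs(elements)
    ehr_plan = _crossover_plan(elements, spec_ids)

    # --- categorical rows: expand pairs, contiguous person blocks ---------
    pair_df = pair_df.sort_values(["element_concept_id", "value_concept_id"], kind="stable",
                                  ignore_index=True)
    elem_rows = pair_df.groupby("element_concept_id", sort=True)["rows"].sum()
    row_elem = np.repeat(pair_df["element_concept_id"].to_numpy(), pair_df["rows"].to_numpy())
    row_val = np.repeat(pair_df["value_concept_id"].to_numpy(), pair_df["rows"].to_numpy())
    order = np.argsort(row_elem, kind="stable")
    row_elem, row_val = row_elem[order], row_val[order]
    starts = np.zeros(len(elem_rows), dtype=np.int64)
    starts[1:] = np.cumsum(elem_rows.to_numpy())[:-1]
    within = np.arange(len(row_elem), dtype=np.int64) - np.repeat(starts, elem_rows.to_numpy())
    person_start = (np.arange(len(elem_rows), dtype=np.int64) * 9973) % TOTAL_PARTICIPANTS
    row_person = (np.repeat(person_start, elem_rows.to_numpy()) + within) % TOTAL_PARTICIPANTS
    ehr_cut = np.array([elem_rows[cid] - (round(0.3 * elem_rows[cid]) if ehr_plan.get(int(cid), 0) == -1
                                          else ehr_plan.get(int(cid), 0))
                        for cid in elem_rows.index], dtype=np.int64)
    is_ehr = within >= np.repeat(ehr_cut, elem_rows.to_numpy())
    site = np.where(is_ehr, "EHR site 130", "PPI/PM")

    observation = pd.DataFrame({
        "observation_id": 1 + np.arange(len(row_elem)),
        "person_id": row_person,
        "observation_concept_id": row_elem,
        "value_as_number": np.nan,
        "value_as_concept_id": row_val,
    })
    observation_ext = pd.DataFrame({"observation_id": observation["observation_id"], "src_id": site})

    # --- numeric rows -----------------------------------------------------
    num_elems = elements[elements["numeric"]]
    m_parts = []
    for k, cid in enumerate(num_elems["concept_id"]):
        cid = int(cid)
        n_ehr = ehr_plan.get(cid, 0)
        n_rows = 25 + max(n_ehr, 0)
        persons = ((cid * 31) % TOTAL_PARTICIPANTS + np.arange(n_rows)) % TOTAL_PARTICIPANTS
        m_parts.append(pd.DataFrame({
            "person_id": persons,
            "measurement_concept_id": cid,
            "value_as_number": 60.0 + (np.arange(n_rows) % 40),
            "value_as_concept_id": 0,
            "src_id": np.where(np.arange(n_rows) < 25, "PPI/PM", "EHR site 131"),
        }))
    measurement = pd.concat(m_parts, ignore_index=True)
    measurement.insert(0, "measurement_id", 1 + np.arange(len(measurement)))
    measurement_ext = measurement[["measurement_id", "src_id"]].copy()
    measurement = measurement.drop(columns="src_id")

    # --- concept catalogue and hierarchy ----------------------------------
    topic_rows, rel_rows = [], []
    next_id = itertools.count(70_000_000)
    for crf, *_ in _CRF_LAYOUT:
        if crf == "No CRF Declared":
            continue
        mod_id = next(next_id)
        topic_rows.append({"concept_id": mod_id, "concept_name": crf, "vocabulary_id": "PPI",
                           "concept_code": f"M-{crf[:8]}", "concept_class_id": "Module",
                           "standard_concept": "S"})
        members = elements[elements["crf"] == crf]
        topic_names = ["Alcohol", f"{crf} topic"] if crf == "Lifestyle" else [f"{crf} topic"]
        topic_ids = {}
        for tname in topic_names:
            tid = next(next_id)
            topic_ids[tname] = tid
            topic_rows.append({"concept_id": tid, "concept_name": tname, "vocabulary_id": "PPI",
                               "concept_code": f"T-{tname[:8]}", "concept_class_id": "Topic",
                               "standard_concept": "S"})
            rel_rows.append({"concept_id_1": tid, "concept_id_2": mod_id,
                             "relationship_id": "Has PPI parent code"})
        for cid, special in zip(members["concept_id"], members["special"]):
            tname = "Alcohol" if special == "alcohol" else topic_names[-1]
            rel_rows.append({"concept_id_1": int(cid), "concept_id_2": topic_ids[tname],
                             "relationship_id": "Has PPI parent code"})

    element_concepts = elements[["concept_id", "concept_name", "vocabulary_id", "concept_code"]].copy()
    element_concepts["concept_class_id"] = "Question"
    element_concepts["standard_concept"] = "S"
    concepts = pd.concat([element_concepts, value_concepts, pd.DataFrame(topic_rows)],
                         ignore_index=True)

    return StudyBundle(
        concepts=concepts,
        relationships=pd.DataFrame(rel_rows),
        measurement=measurement,
        observation=observation,
        measurement_ext=measurement_ext,
        observation_ext=observation_ext,
        initiatives=initiatives,
        total_participants=TOTAL_PARTICIPANTS,
        metadata={"kind": "reference-marginals", "synthetic": True},
    )
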