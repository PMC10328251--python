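"""Synthetic OMOP-shaped study generator with planted ground truth.

The generator emulates the structure of a survey-plus-EHR cohort study held
in OMOP CDM form: a concept catalogue mixing established vocabularies
(LOINC, SNOMED, UCUM) with study-custom ones (PPI, AoU_General), categorical
question elements with finite answer sets including a skip concept, numeric
elements, a CRF hierarchy (element -> topic -> module) in
CONCEPT_RELATIONSHIP, and per-row source labels splitting research-visit
(CRF) rows from EHR-site rows.

Category counts (how many elements per vocabulary, numeric vs categorical,
skip-enabled, crossover, per-CRF) are planted by exact largest-remainder
allocation from the configured proportions — never sampled — so pipeline
recovery tests compare exactly against the emitted :class:`GroundTruth`.
The seed only permutes identifiers and drives per-row answer draws; the
per-element truth is recorded from the rows actually written.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

from .bundle import StudyBundle
from .elements import NO_CRF

SKIP_CONCEPT_ID = 903096
PREFER_NOT_CONCEPT_ID = 1177221


class GeneratorConfig(BaseModel):
    """Knobs of the synthetic study.

    Defaults mirror the composition observed in a large national cohort's
    CRF data: ~84% study-custom (PPI) elements, ~10% LOINC, ~6% SNOMED, 4%
    numeric elements, ~72% of elements skip-enabled, ~6% of elements with
    EHR crossover, ~30% of elements outside any CRF.
    """

    seed: int = 0
    n_participants: int = Field(default=500, ge=1)
    n_elements: int = Field(default=100, ge=1)
    vocabulary_mixture: dict[str, float] = {"LOINC": 0.100, "SNOMED": 0.058, "UCUM": 0.001, "PPI": 0.841}
    numeric_fraction: float = Field(default=0.04, ge=0, le=1)
    values_per_element: tuple[int, int] = (2, 8)
    skip_enabled_fraction: float = Field(default=0.72, ge=0, le=1)
    avoidance_use_rate: float = Field(default=0.02, ge=0, le=1)
    crossover_fraction: float = Field(default=0.06, ge=0, le=1)
    ehr_row_share: float = Field(default=0.3, ge=0, le=1)
    initiative_fraction: float = Field(default=0.84, ge=0, le=1)
    n_modules: int = Field(default=5, ge=1)
    topics_per_module: int = Field(default=2, ge=1)
    no_crf_fraction: float = Field(default=0.30, ge=0, le=1)
    rows_per_element: int = Field(default=30, ge=1)
    custom_vocabularies: frozenset[str] = frozenset({"PPI", "AoU_General"})

    model_config = {"frozen": True}

    @model_validator(mode="after")
    def _validate(self):
        if abs(sum(self.vocabulary_mixture.values()) - 1.0) > 1e-9:
            raise ValueError("vocabulary_mixture must sum to 1")
        lo, hi = self.values_per_element
        if lo < 1 or hi < lo:
            raise ValueError("values_per_element must satisfy 1 <= min <= max")
        if self.rows_per_element < hi + 1:
            raise ValueError("rows_per_element must exceed the maximum answer-set size "
                             "so every planted value can be observed")
        if self.rows_per_element > self.n_participants:
            raise ValueError("rows_per_element cannot exceed n_participants "
                             "(participants are assigned as a contiguous block)")
        return self


@dataclass
class GroundTruth:
    """What was planted, recorded from the rows actually emitted."""

    per_element: pd.DataFrame   # concept_id, vocabulary_id, origin_class, data_type, crf,
                                # topic, initiative, n_rows, n_participants, crf_rows,
                                # ehr_rows, n_values, skip_enabled
    pair_counts: pd.DataFrame   # element_concept_id, value_concept_id, count
    globals: dict               # aggregated truths

    @staticmethod
    def aggregate(per_element: pd.DataFrame) -> dict:
        by_crf = per_element.groupby("crf").size().to_dict()
        return {
            "n_elements": int(len(per_element)),
            "cde_count": int((per_element["origin_class"] == "CDE").sum()),
            "ude_count": int((per_element["origin_class"] == "UDE").sum()),
            "numeric_count": int((per_element["data_type"] == "numeric").sum()),
            "categorical_count": int((per_element["data_type"] == "categorical").sum()),
            "skip_enabled_count": int(per_element["skip_enabled"].sum()),
            "crossover_count": int(((per_element["crf_rows"] > 0) & (per_element["ehr_rows"] > 0)).sum()),
            "per_crf_counts": {str(k): int(v) for k, v in by_crf.items()},
            "n_event_rows": int(per_element["n_rows"].sum()),
        }


def largest_remainder(proportions: dict[str, float], total: int) -> dict[str, int]:
    """Integer allocation of ``total`` by proportions, exact and deterministic.

    Floors every share and hands the remaining units to the largest
    fractional parts (ties broken by key order) so the counts always sum to
    ``total``.
    """
    keys = list(proportions)
    raw = np.array([proportions[k] * total for k in keys], dtype=float)
    base = np.floor(raw).astype(int)
    short = total - int(base.sum())
    order = sorted(range(len(keys)), key=lambda i: (-(raw[i] - base[i]), i))
    for i in order[:short]:
        base[i] += 1
    return dict(zip(keys, base.tolist()))


_INITIATIVES = ("PhenX", "PROMIS", "PHQ", "SAMHSA")


def generate_study(config: GeneratorConfig) -> tuple[StudyBundle, GroundTruth]:
    """Emit one OMOP table bundle plus its ground-truth manifest."""
    rng = np.random.default_rng(config.seed)
    n = config.n_elements

    # -- category allocation (exact, config-driven; seed only permutes) ----
    vocab_counts = largest_remainder(config.vocabulary_mixture, n)
    vocab_labels = np.repeat(list(vocab_counts), list(vocab_counts.values()))
    n_numeric = int(round(config.numeric_fraction * n))
    n_categorical = n - n_numeric
    n_skip = min(int(round(config.skip_enabled_fraction * n)), n_categorical)
    n_cross = int(round(config.crossover_fraction * n))
    n_no_crf = min(int(round(config.no_crf_fraction * n)), n)

    perm = rng.permutation(n)  # element slot -> attribute slot
    element_ids = 10_000_000 + np.arange(n)
    rng.shuffle(element_ids)
    vocab_by_elem = vocab_labels[perm]
    # numeric flag on the first slots, skip-enabled on the first categorical
    # slots, crossover/no-CRF round-robin: all through the same permutation
    numeric_flag = np.zeros(n, dtype=bool)
    numeric_flag[perm < n_numeric] = True
    skip_flag = np.zeros(n, dtype=bool)
    cat_positions = np.where(~numeric_flag)[0]
    skip_flag[cat_positions[np.argsort(perm[cat_positions])][:n_skip]] = True
    cross_flag = np.isin(perm, np.arange(n_cross))
    no_crf_flag = np.isin(perm, n - 1 - np.arange(n_no_crf))

    # -- hierarchy concepts -----------------------------------------------
    module_ids = 20_000_000 + np.arange(config.n_modules)
    topic_ids = 21_000_000 + np.arange(config.n_modules * config.topics_per_module)
    topic_module = np.repeat(np.arange(config.n_modules), config.topics_per_module)
    assigned = np.where(~no_crf_flag)[0]
    topic_of_elem = np.full(n, -1)
    topic_of_elem[assigned] = np.arange(len(assigned)) % len(topic_ids)

    # -- value concepts ----------------------------------------------------
    shared_pool_vocab = ["LOINC", "SNOMED", "PPI", "SNOMED", "LOINC", "PPI", "SNOMED", "AoU_General", "LOINC", "SNOMED"]
    shared_ids = 30_000_000 + np.arange(len(shared_pool_vocab))
    value_rows: list[tuple[int, str, str]] = [
        (SKIP_CONCEPT_ID, "PPI", "Answer"),
        (PREFER_NOT_CONCEPT_ID, "LOINC", "Answer"),
    ] + [(int(v), shared_pool_vocab[i], "Answer") for i, v in enumerate(shared_ids)]
    lo, hi = config.values_per_element
    span = hi - lo + 1
    next_unique = 31_000_000
    value_sets: dict[int, list[int]] = {}
    for i in range(n):
        if numeric_flag[i]:
            continue
        k = lo + int(perm[i]) % span
        vals = [int(shared_ids[int(perm[i]) % len(shared_ids)])]
        n_unique = max(0, k - 1 - int(skip_flag[i]))
        for _ in range(n_unique):
            vocab = ["PPI", "SNOMED", "LOINC"][next_unique % 3]
            value_rows.append((next_unique, vocab, "Answer"))
            vals.append(next_unique)
            next_unique += 1
        if skip_flag[i]:
            vals.append(SKIP_CONCEPT_ID)
        value_sets[i] = vals

    # -- initiative lookup over LOINC elements -----------------------------
    loinc_idx = np.where(vocab_by_elem == "LOINC")[0]
    n_init = int(round(config.initiative_fraction * len(loinc_idx)))
    codes = {i: f"SYN{int(eid) % 1_000_000}-{j % 10}" for j, (i, eid) in enumerate(zip(range(n), element_ids))}
    initiative_of: dict[int, str] = {}
    for j, i in enumerate(loinc_idx[:n_init]):
        initiative_of[int(i)] = _INITIATIVES[j % len(_INITIATIVES)]

    # -- event rows --------------------------------------------------------
    rows = config.rows_per_element
    recs = {"element": [], "person": [], "vnum": [], "vconc": [], "src": []}
    per_elem_truth = []
    pair_counts: dict[tuple[int, int], int] = {}
    for i in range(n):
        eid = int(element_ids[i])
        start = int((i * 17) % max(1, config.n_participants - rows + 1))
        persons = start + np.arange(rows)
        n_ehr = 0
        if cross_flag[i]:
            n_ehr = min(rows - 1, max(1, int(round(config.ehr_row_share * rows))))
        src = np.array(["PPI/PM"] * (rows - n_ehr) + [f"EHR site {100 + i % 7}"] * n_ehr)
        if numeric_flag[i]:
            vnum = np.round(rng.normal(50, 10, size=rows), 2)
            vconc = np.zeros(rows, dtype=int)
        else:
            vals = value_sets[i]
            substantive = [v for v in vals if v != SKIP_CONCEPT_ID]
            draw = rng.random(rows - len(vals))
            extra = np.where(
                skip_flag[i] & (draw < config.avoidance_use_rate),
                SKIP_CONCEPT_ID,
                np.asarray(substantive)[rng.integers(0, len(substantive), size=rows - len(vals))],
            )
            vconc = np.concatenate([np.asarray(vals, dtype=int), extra.astype(int)])
            vnum = np.full(rows, np.nan)
            ids, cnts = np.unique(vconc, return_counts=True)
            for v, c in zip(ids, cnts):
                pair_counts[(eid, int(v))] = int(c)
        recs["element"].append(np.full(rows, eid))
        recs["person"].append(persons)
        recs["vnum"].append(vnum)
        recs["vconc"].append(vconc)
        recs["src"].append(src)
        t_idx = topic_of_elem[i]
        per_elem_truth.append({
            "concept_id": eid,
            "vocabulary_id": vocab_by_elem[i],
            "origin_class": "UDE" if vocab_by_elem[i] in config.custom_vocabularies else "CDE",
            "data_type": "numeric" if numeric_flag[i] else "categorical",
            "crf": NO_CRF if t_idx < 0 else f"Module {topic_module[t_idx] + 1}",
            "topic": None if t_idx < 0 else f"Topic {t_idx + 1}",
            "initiative": initiative_of.get(i),
            "n_rows": rows,
            "n_participants": rows,
            "crf_rows": rows - n_ehr,
            "ehr_rows": n_ehr,
            "n_values": 0 if numeric_flag[i] else len(value_sets[i]),
            "skip_enabled": bool(skip_flag[i]),
        })

    events = pd.DataFrame({
        "element_concept_id": np.concatenate(recs["element"]),
        "person_id": np.concatenate(recs["person"]),
        "value_as_number": np.concatenate(recs["vnum"]),
        "value_as_concept_id": np.concatenate(recs["vconc"]),
        "src_id": np.concatenate(recs["src"]),
    })
    is_meas = events["element_concept_id"].isin(element_ids[numeric_flag]).to_numpy()
    measurement = events[is_meas].reset_index(drop=True)
    observation = events[~is_meas].reset_index(drop=True)
    measurement.insert(0, "measurement_id", 1 + np.arange(len(measurement)))
    observation.insert(0, "observation_id", 1 + np.arange(len(observation)))
    measurement = measurement.rename(columns={"element_concept_id": "measurement_concept_id"})
    observation = observation.rename(columns={"element_concept_id": "observation_concept_id"})
    measurement_ext = measurement[["measurement_id", "src_id"]].copy()
    observation_ext = observation[["observation_id", "src_id"]].copy()
    measurement = measurement.drop(columns="src_id")
    observation = observation.drop(columns="src_id")

    # -- concept catalogue -------------------------------------------------
    concept_rows = []
    for i in range(n):
        concept_rows.append({
            "concept_id": int(element_ids[i]), "concept_name": f"Synthetic element {i + 1}",
            "vocabulary_id": vocab_by_elem[i],
            "concept_code": codes[i] if vocab_by_elem[i] == "LOINC" else f"SC{i}",
            "concept_class_id": "Question", "standard_concept": "S"})
    for vid, vocab, cls in value_rows:
        name = {SKIP_CONCEPT_ID: "PMI: Skip", PREFER_NOT_CONCEPT_ID: "I prefer not to answer"}.get(
            vid, f"Synthetic value {vid}")
        concept_rows.append({"concept_id": vid, "concept_name": name, "vocabulary_id": vocab,
                             "concept_code": f"V{vid}", "concept_class_id": cls, "standard_concept": "S"})
    for j, tid in enumerate(topic_ids):
        concept_rows.append({"concept_id": int(tid), "concept_name": f"Topic {j + 1}",
                             "vocabulary_id": "PPI", "concept_code": f"T{j}",
                             "concept_class_id": "Topic", "standard_concept": "S"})
    for j, mid in enumerate(module_ids):
        concept_rows.append({"concept_id": int(mid), "concept_name": f"Module {j + 1}",
                             "vocabulary_id": "PPI", "concept_code": f"M{j}",
                             "concept_class_id": "Module", "standard_concept": "S"})
    concepts = pd.DataFrame(concept_rows)

    rel_rows = []
    for i in range(n):
        t_idx = topic_of_elem[i]
        if t_idx >= 0:
            rel_rows.append({"concept_id_1": int(element_ids[i]), "concept_id_2": int(topic_ids[t_idx]),
                             "relationship_id": "Has PPI parent code"})
    for t_idx, tid in enumerate(topic_ids):
        rel_rows.append({"concept_id_1": int(tid), "concept_id_2": int(module_ids[topic_module[t_idx]]),
                         "relationship_id": "Has PPI parent code"})
    relationships = pd.DataFrame(rel_rows)

    initiatives = pd.DataFrame(
        [{"loinc_code": codes[i], "initiative": lab} for i, lab in sorted(initiative_of.items())]
    ) if initiative_of else pd.DataFrame(columns=["loinc_code", "initiative"])

    truth_frame = pd.DataFrame(per_elem_truth)
    pairs = pd.DataFrame(
        [{"element_concept_id": e, "value_concept_id": v, "count": c}
         for (e, v), c in sorted(pair_counts.items())])
    truth = GroundTruth(truth_frame, pairs, GroundTruth.aggregate(truth_frame))
    bundle = StudyBundle(
        concepts=concepts, relationships=relationships,
        measurement=measurement, observation=observation,
        measurement_ext=measurement_ext, observation_ext=observation_ext,
        initiatives=initiatives, total_participants=config.n_participants,
        metadata={"generator_seed": config.seed, "n_elements": n},
    )
    return bundle, truth
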