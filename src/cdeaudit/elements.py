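"""Data-element dictionary construction.

One *element* is a distinct measurement/observation concept used to collect
data.  For each element the dictionary records usage volume (event rows),
participant coverage (distinct persons), its origin class — CDE if the
concept comes from an established terminology (LOINC, SNOMED, UCUM, ...),
UDE if it was minted in the study's custom vocabularies — its data type
(numeric if strictly more than half of its rows carry ``value_as_number``,
else categorical), the prior data-collection initiative it originated from
(PhenX, PROMIS, ... via the LOINC code), and the CRF it belongs to, found by
walking the concept-relationship hierarchy upward: element -> topic -> module.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd

from ._util import round_half_up
from .config import ProfileConfig, DEFAULT_CONFIG
from .io import ConceptCatalogue, EventStore, RelationshipGraph

NO_CRF = "No CRF Declared"


class HierarchyCycleError(ValueError):
    """A cycle in the CRF hierarchy makes upward traversal ill-defined."""


def classify_element_origin(vocabulary_id: str, config: ProfileConfig = DEFAULT_CONFIG) -> str:
    """CDE/UDE split: UDE iff the element's vocabulary is study-custom."""
    return "UDE" if vocabulary_id in config.custom_vocabularies else "CDE"


def classify_data_type(events_for_element) -> str:
    """Numeric iff strictly more than half the rows have value_as_number.

    ``events_for_element`` is a frame (column ``value_as_number``) or a
    sequence of optional numbers.  Exactly half numeric is categorical —
    the majority must be strict.
    """
    if isinstance(events_for_element, pd.DataFrame):
        vals = events_for_element["value_as_number"]
    else:
        vals = pd.Series(list(events_for_element), dtype="float64")
    n = len(vals)
    if n == 0:
        raise ValueError("an element cannot exist without data rows")
    return "numeric" if vals.notna().sum() * 2 > n else "categorical"


def map_initiative(vocabulary_id: str, concept_code: str, lookup: dict[str, str],
                   config: ProfileConfig = DEFAULT_CONFIG) -> str | None:
    """Initiative provenance via the LOINC code; UDEs never get one."""
    if classify_element_origin(vocabulary_id, config) != "CDE" or vocabulary_id != "LOINC":
        return None
    return lookup.get(concept_code)


def assign_crf(element_concept_id: int, graph: RelationshipGraph, concepts: ConceptCatalogue,
               config: ProfileConfig = DEFAULT_CONFIG) -> str:
    """CRF label for one element (module concept name, or "No CRF Declared")."""
    crf, _topic, _amb = _traverse(element_concept_id, graph, concepts, config)
    return crf


def _traverse(element_id: int, graph: RelationshipGraph, concepts: ConceptCatalogue,
              config: ProfileConfig) -> tuple[str, str | None, bool]:
    """Breadth-first upward walk; returns (crf, topic, ambiguous).

    The first concept of the topic class encountered is the topic; the
    nearest concept of the module class is the CRF.  A tie at the same
    depth resolves to the lexicographically smallest module name and is
    flagged ambiguous.  Traversal depth is bounded; a cycle among the
    followed edges is an error.
    """
    topic: str | None = None
    modules_at_depth: list[str] = []
    seen = {element_id}
    frontier = deque([(element_id, 0)])
    module_depth = None
    while frontier:
        node, depth = frontier.popleft()
        if depth >= config.max_hierarchy_depth:
            continue
        if module_depth is not None and depth >= module_depth:
            break
        for nxt in graph.successors(node, config.crf_relationship_ids):
            if nxt in seen:
                _check_cycle(element_id, graph, config)
                continue
            seen.add(nxt)
            if nxt not in concepts:
                continue
            cls = concepts.class_of(nxt)
            if cls == config.topic_class and topic is None:
                topic = concepts.name_of(nxt)
            if cls == config.module_class:
                modules_at_depth.append(concepts.name_of(nxt))
                module_depth = depth + 1
            frontier.append((nxt, depth + 1))
    if not modules_at_depth:
        return NO_CRF, topic, False
    ambiguous = len(set(modules_at_depth)) > 1
    return min(modules_at_depth), topic, ambiguous


def _check_cycle(element_id: int, graph: RelationshipGraph, config: ProfileConfig) -> None:
    """Revisiting a node may just be a diamond; error only on a true cycle."""
    wanted = set(config.crf_relationship_ids)
    sub = nx.DiGraph((u, v) for u, v, k in graph.graph.edges(keys=True) if k in wanted)
    try:
        cycle = nx.find_cycle(sub, source=element_id)
    except nx.NetworkXNoCycle:
        return
    raise HierarchyCycleError(f"cycle in CRF hierarchy starting at {element_id}: {cycle}")


def build_element_dictionary(
    events: EventStore,
    concepts: ConceptCatalogue,
    config: ProfileConfig = DEFAULT_CONFIG,
    total_participants: int | None = None,
    graph: RelationshipGraph | None = None,
    initiative_lookup: dict[str, str] | None = None,
) -> pd.DataFrame:
    """One row per distinct element concept observed in the store.

    ``participant_pct`` uses ``total_participants`` as denominator when
    supplied (e.g. the enrolled cohort size), else the distinct persons seen
    in the store.  CRF assignment and initiative mapping are filled when a
    relationship graph / lookup are given, else left as "No CRF Declared" /
    missing.
    """
    ev = events.events
    if len(ev) == 0:
        return pd.DataFrame(columns=[
            "concept_id", "concept_name", "vocabulary_id", "concept_code", "event_count",
            "participant_count", "participant_pct", "origin_class", "data_type",
            "initiative", "crf", "topic", "crf_ambiguous", "sources"])
    grouped = ev.groupby("element_concept_id", sort=True)
    agg = grouped.agg(
        event_count=("event_id", "size"),
        participant_count=("person_id", "nunique"),
        n_numeric=("value_as_number", "count"),
    ).reset_index().rename(columns={"element_concept_id": "concept_id"})
    denom = total_participants if total_participants else ev["person_id"].nunique()
    agg["participant_pct"] = round_half_up(agg["participant_count"] / denom * 100.0, config.table_percent_decimals)
    agg["data_type"] = np.where(agg["n_numeric"] * 2 > agg["event_count"], "numeric", "categorical")
    agg = agg.drop(columns="n_numeric")

    unresolved = set(agg["concept_id"]) - set(concepts.frame.index)
    if unresolved:
        raise ValueError(f"element concept id(s) not in catalogue: {sorted(unresolved)[:10]}")
    for col in ("concept_name", "vocabulary_id", "concept_code"):
        agg[col] = concepts.lookup(agg["concept_id"], col).to_numpy()
    agg["origin_class"] = np.where(agg["vocabulary_id"].isin(config.custom_vocabularies), "UDE", "CDE")

    lookup = initiative_lookup or {}
    agg["initiative"] = [
        map_initiative(v, c, lookup, config) for v, c in zip(agg["vocabulary_id"], agg["concept_code"])
    ]
    if graph is not None:
        trav = [_traverse(int(cid), graph, concepts, config) for cid in agg["concept_id"]]
        agg["crf"] = [t[0] for t in trav]
        agg["topic"] = [t[1] for t in trav]
        agg["crf_ambiguous"] = [t[2] for t in trav]
    else:
        agg["crf"], agg["topic"], agg["crf_ambiguous"] = NO_CRF, None, False
    agg["sources"] = grouped["src_id"].agg(lambda s: tuple(sorted(set(s)))).to_numpy()
    cols = ["concept_id", "concept_name", "vocabulary_id", "concept_code", "event_count",
            "participant_count", "participant_pct", "origin_class", "data_type",
            "initiative", "crf", "topic", "crf_ambiguous", "sources"]
    return agg[cols]


@dataclass
class DictionarySummary:
    """Aggregate view of an element dictionary (counts and shares)."""

    total_elements: int
    by_vocabulary: pd.DataFrame     # vocabulary_id, elements, pct
    by_origin: dict[str, int]       # CDE / UDE counts
    by_data_type: dict[str, int]    # numeric / categorical counts
    by_initiative: pd.DataFrame     # initiative, elements, pct_of_initiative_cdes
    by_crf: pd.DataFrame            # crf, elements, pct_of_total, udes, cdes


def summarize_dictionary(records: pd.DataFrame, config: ProfileConfig = DEFAULT_CONFIG) -> DictionarySummary:
    """Roll the element dictionary up into the headline tables.

    Vocabulary and initiative shares use the narrative rounding
    (``percent_decimals``); per-CRF shares use the table rounding
    (``table_percent_decimals``).
    """
    if len(records) == 0:
        raise ValueError("cannot summarize an empty element dictionary")
    total = len(records)
    by_vocab = (records.groupby("vocabulary_id").size().rename("elements").reset_index()
                .sort_values(["elements", "vocabulary_id"], ascending=[False, True], ignore_index=True))
    by_vocab["pct"] = round_half_up(by_vocab["elements"] / total * 100.0, config.percent_decimals)
    by_origin = records["origin_class"].value_counts().to_dict()
    by_type = records["data_type"].value_counts().to_dict()
    init = records.dropna(subset=["initiative"])
    by_init = (init.groupby("initiative").size().rename("elements").reset_index()
               .sort_values(["elements", "initiative"], ascending=[False, True], ignore_index=True))
    n_init = len(init)
    by_init["pct_of_initiative_cdes"] = round_half_up(
        by_init["elements"] / n_init * 100.0, config.table_percent_decimals) if n_init else 0.0
    by_crf = (records.groupby("crf")
              .agg(elements=("concept_id", "size"),
                   udes=("origin_class", lambda s: int((s == "UDE").sum())),
                   cdes=("origin_class", lambda s: int((s == "CDE").sum())))
              .reset_index()
              .sort_values(["elements", "crf"], ascending=[False, True], ignore_index=True))
    by_crf["pct_of_total"] = round_half_up(by_crf["elements"] / total * 100.0, config.table_percent_decimals)
    by_crf = by_crf[["crf", "elements", "pct_of_total", "udes", "cdes"]]
    return DictionarySummary(total, by_vocab, by_origin, by_type, by_init, by_crf)
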