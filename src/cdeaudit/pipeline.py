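"""End-to-end audit pipeline.

``profile_study`` runs the whole audit over one study bundle: scope the
event store to CRF elements (elements with at least one research-visit row),
build the element dictionary, the permissible-value tables, the avoidance
report, the terminology concordance, the CRF/EHR crossover list and the
two-axis classification.  Small-cell suppression is applied when the result
is rendered to files, not while profiling, so internal consistency checks
can see every row.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import pandas as pd

from . import crossover as xo
from . import elements as el
from . import values as val
from .bundle import StudyBundle
from .config import ProfileConfig, DEFAULT_CONFIG
from .io import ConceptCatalogue, EventStore, RelationshipGraph


@dataclass
class ProfileResult:
    """Everything the audit computes for one study."""

    config: ProfileConfig
    total_participants: int
    elements: pd.DataFrame
    summary: el.DictionarySummary
    pairs: pd.DataFrame
    values: pd.DataFrame
    avoidance: val.AvoidanceReport
    terminology_profile: pd.DataFrame
    concordance: pd.DataFrame
    concordance_summary: dict[str, int]
    source_counts: pd.DataFrame
    crossover: pd.DataFrame
    axes: xo.AxisClassification
    numeric_coded_diagnostics: pd.DataFrame
    dropped_ext_rows: pd.DataFrame = field(default_factory=pd.DataFrame)


def profile_events(
    events: EventStore,
    concepts: ConceptCatalogue,
    graph: RelationshipGraph | None = None,
    initiative_lookup: dict[str, str] | None = None,
    config: ProfileConfig = DEFAULT_CONFIG,
    total_participants: int | None = None,
    healthcare_elements: set[int] | None = None,
    crf_only: bool = True,
) -> ProfileResult:
    """Profile an event store that is already in memory."""
    ev = events.events
    src = xo.source_counts(events, config)
    if crf_only:
        crf_elems = set(src.loc[src["crf_event_count"] > 0, "element_concept_id"])
        ev = ev[ev["element_concept_id"].isin(crf_elems)]
        events = EventStore(ev.reset_index(drop=True), events.dropped_ext_rows)
        src = src[src["element_concept_id"].isin(crf_elems)].reset_index(drop=True)
    records = el.build_element_dictionary(
        events, concepts, config, total_participants=total_participants,
        graph=graph, initiative_lookup=initiative_lookup)
    summary = el.summarize_dictionary(records, config)
    pairs = val.build_element_value_table(events, concepts, records, config)
    values = val.build_value_dictionary(pairs, concepts, config)
    avoidance = val.detect_answer_avoidance(pairs, config, total_elements=len(records))
    term_profile = val.value_terminology_profile(values, pairs, concepts, config, total_elements=len(records))
    concordance, concordance_summary = val.element_value_concordance(records, pairs, concepts, config)
    crossover = xo.find_crossover_elements(events, config)
    axes = xo.classify_axes(records, crossover, healthcare_elements)
    diag = val.numeric_element_coded_rows(events, records)
    denom = total_participants if total_participants else events.events["person_id"].nunique()
    return ProfileResult(
        config=config,
        total_participants=int(denom),
        elements=records,
        summary=summary,
        pairs=pairs,
        values=values,
        avoidance=avoidance,
        terminology_profile=term_profile,
        concordance=concordance,
        concordance_summary=concordance_summary,
        source_counts=src,
        crossover=crossover,
        axes=axes,
        numeric_coded_diagnostics=diag,
        dropped_ext_rows=events.dropped_ext_rows,
    )


def profile_study(
    bundle: StudyBundle,
    config: ProfileConfig = DEFAULT_CONFIG,
    total_participants: int | None = None,
    healthcare_elements: set[int] | None = None,
    crf_only: bool = True,
) -> ProfileResult:
    """Profile a study bundle (in memory or loaded from disk)."""
    concepts = bundle.concept_catalogue()
    graph = bundle.relationship_graph()
    events = bundle.event_store(config)
    lookup = bundle.initiative_lookup()
    if total_participants is None:
        total_participants = bundle.total_participants
    return profile_events(
        events, concepts, graph=graph, initiative_lookup=lookup, config=config,
        total_participants=total_participants, healthcare_elements=healthcare_elements,
        crf_only=crf_only)
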