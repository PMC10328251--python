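"""CRF vs EHR source attribution and crossover analysis.

Each data row carries a ``src_id``: research-visit / CRF rows are labelled
with the study's CRF source label(s), every other label is an EHR site.  A
*crossover element* has at least one row from each side — typically a
question first answered on a CRF and later updated through EHR import.
Crossover identity is by exact concept id (no semantic mapping of source
codes).  The two-axis classification splits CDEs by origin (healthcare vs
research) and by ingestion into a routine healthcare terminology; UDEs sit
outside the classification.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up
from .config import ProfileConfig, DEFAULT_CONFIG
from .io import EventStore


def attribute_source(src_id: str | None, config: ProfileConfig = DEFAULT_CONFIG) -> str:
    """CRF iff the row's src_id is one of the configured CRF labels."""
    if src_id is None or (isinstance(src_id, float) and pd.isna(src_id)):
        if config.strict_src_id:
            raise ValueError("event without src_id in strict mode")
        return "EHR"
    return "CRF" if src_id in config.crf_src_ids else "EHR"


def source_counts(events: EventStore, config: ProfileConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Per element: rows from CRF and rows from EHR sources."""
    ev = events.events
    if config.strict_src_id and ev["src_id"].isna().any():
        raise ValueError("events without src_id in strict mode")
    is_crf = ev["src_id"].isin(config.crf_src_ids)
    out = (pd.DataFrame({"element_concept_id": ev["element_concept_id"], "is_crf": is_crf})
           .groupby("element_concept_id")["is_crf"]
           .agg(crf_event_count="sum", ehr_event_count=lambda s: int((~s).sum()))
           .reset_index())
    out["crf_event_count"] = out["crf_event_count"].astype(int)
    out["pct_from_crf"] = round_half_up(
        out["crf_event_count"] / (out["crf_event_count"] + out["ehr_event_count"]) * 100.0,
        config.table_percent_decimals)
    return out


def find_crossover_elements(events: EventStore, config: ProfileConfig = DEFAULT_CONFIG) -> pd.DataFrame:
    """Elements with rows from both the CRF source and at least one EHR site."""
    counts = source_counts(events, config)
    both = (counts["crf_event_count"] > 0) & (counts["ehr_event_count"] > 0)
    return counts[both].reset_index(drop=True)


@dataclass
class AxisClassification:
    """Two-axis origin × ingestion cell counts over CDEs."""

    cells: pd.DataFrame          # origin, ingestion, element_count
    ude_count: int               # outside the classification
    healthcare_total: int | None  # O1 row total, only when an EHR universe is known

    def cell(self, origin: str, ingestion: str) -> int:
        m = self.cells[(self.cells["origin"] == origin) & (self.cells["ingestion"] == ingestion)]
        return int(m["element_count"].iloc[0]) if len(m) else 0


def classify_axes(
    element_records: pd.DataFrame,
    crossover: pd.DataFrame,
    healthcare_elements: set[int] | None = None,
) -> AxisClassification:
    """Partition CDEs into origin × ingestion cells.

    A CDE observed in routine healthcare (member of ``healthcare_elements``
    when supplied, else present in the crossover list) is
    O1-healthcare-T1-ingested; the remaining CDEs are
    O2-research-T1-ingested.  With the study's element universe drawn from
    OMOP-ingested terminologies, O2-research-T2-non-ingested is structurally
    empty but still reported.  The O1 row total (healthcare elements beyond
    the study's CRF scope) is only known when a universe is supplied.
    """
    cdes = element_records[element_records["origin_class"] == "CDE"]
    in_healthcare = healthcare_elements if healthcare_elements is not None else set(
        crossover["element_concept_id"]) if len(crossover) else set()
    o1 = int(cdes["concept_id"].isin(in_healthcare).sum())
    o2 = len(cdes) - o1
    cells = pd.DataFrame([
        {"origin": "O1-healthcare", "ingestion": "T1-ingested", "element_count": o1},
        {"origin": "O2-research", "ingestion": "T1-ingested", "element_count": o2},
        {"origin": "O2-research", "ingestion": "T2-non-ingested", "element_count": 0},
    ])
    return AxisClassification(
        cells=cells,
        ude_count=int((element_records["origin_class"] == "UDE").sum()),
        healthcare_total=len(healthcare_elements) if healthcare_elements is not None else None,
    )
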