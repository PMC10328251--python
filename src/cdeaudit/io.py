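"""Reading and validating OMOP CDM vocabulary and clinical tables.

The audit consumes four OMOP CDM v5.x tables as delimited text — CONCEPT,
CONCEPT_RELATIONSHIP, MEASUREMENT and OBSERVATION — plus optional
MEASUREMENT_EXT / OBSERVATION_EXT side tables carrying the per-row ``src_id``
source label, and an optional LOINC-code → initiative lookup.  Everything is
held in memory as pandas frames: a :class:`ConceptCatalogue` (the vocabulary
layer), an :class:`EventStore` (measurement and observation rows unified into
"clinical events") and a :class:`RelationshipGraph` (a directed multigraph
over concepts, used for CRF assignment).

Files are comma-separated UTF-8 with a header row by default; tab-separated
input is accepted via ``sep="\\t"``.  OMOP column names are matched
case-insensitively.  A missing / zero ``value_as_concept_id`` is normalized
to the explicit NONE sentinel (concept id 0) so that "no coded value" is a
first-class permissible value downstream.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import pandas as pd

from .config import NONE_VALUE_ID, NONE_VOCABULARY, ProfileConfig, DEFAULT_CONFIG

CONCEPT_REQUIRED = ("concept_id", "concept_name", "vocabulary_id", "concept_code", "concept_class_id")
RELATIONSHIP_REQUIRED = ("concept_id_1", "concept_id_2", "relationship_id")
EVENT_COLUMNS = ("event_id", "person_id", "element_concept_id", "domain", "value_as_number", "value_as_concept_id", "src_id")


class OmopIOError(ValueError):
    """Raised when an input table violates the OMOP contract."""


def _read_table(path: str | Path, sep: str = ",") -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype_backend="numpy_nullable")
    df.columns = [c.strip().lower() for c in df.columns]
    return df


def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise OmopIOError(f"{path}: missing required column(s) {missing}")


class ConceptCatalogue:
    """The OMOP CONCEPT table keyed by concept_id.

    Each concept belongs to exactly one vocabulary (``vocabulary_id``); the
    catalogue always contains the NONE sentinel (id 0, vocabulary "None")
    so coded-value-absent rows resolve like any other value.
    """

    def __init__(self, frame: pd.DataFrame):
        frame = frame.copy()
        dup = frame["concept_id"][frame["concept_id"].duplicated()]
        if len(dup):
            raise OmopIOError(f"duplicate concept_id(s): {sorted(set(dup.tolist()))}")
        if (frame["vocabulary_id"].isna() | (frame["vocabulary_id"].astype(str) == "")).any():
            raise OmopIOError("vocabulary_id must be non-empty for every concept")
        frame["concept_id"] = frame["concept_id"].astype("int64")
        frame["concept_code"] = frame["concept_code"].fillna("").astype(str)
        frame["concept_name"] = frame["concept_name"].fillna("").astype(str)
        if NONE_VALUE_ID not in set(frame["concept_id"]):
            sentinel = pd.DataFrame(
                [{"concept_id": NONE_VALUE_ID, "concept_name": "None", "vocabulary_id": NONE_VOCABULARY,
                  "concept_code": "", "concept_class_id": "Value", "standard_concept": ""}]
            )
            frame = pd.concat([frame, sentinel[frame.columns.intersection(sentinel.columns)]], ignore_index=True)
        self.frame = frame.set_index("concept_id", drop=False).sort_index()

    def __len__(self) -> int:
        # the synthetic sentinel is not a catalogue row
        return int((self.frame["concept_id"] != NONE_VALUE_ID).sum())

    def __contains__(self, concept_id: int) -> bool:
        return concept_id in self.frame.index

    def vocabulary_of(self, concept_id: int) -> str:
        return str(self.frame.at[concept_id, "vocabulary_id"])

    def name_of(self, concept_id: int) -> str:
        return str(self.frame.at[concept_id, "concept_name"])

    def code_of(self, concept_id: int) -> str:
        return str(self.frame.at[concept_id, "concept_code"])

    def class_of(self, concept_id: int) -> str:
        return str(self.frame.at[concept_id, "concept_class_id"])

    def lookup(self, concept_ids, column: str) -> pd.Series:
        """Vectorized attribute lookup for a sequence of concept ids."""
        return self.frame[column].reindex(pd.Index(concept_ids))


@dataclass
class EventStore:
    """Unified MEASUREMENT + OBSERVATION rows ("clinical events").

    ``events`` has the columns in :data:`EVENT_COLUMNS`; ``dropped_ext_rows``
    itemizes source-extension rows that referenced unknown event ids, so
    event-count conservation (|store| = measurement rows + observation rows)
    is auditable.
    """

    events: pd.DataFrame
    dropped_ext_rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __len__(self) -> int:
        return len(self.events)

    def __post_init__(self):
        missing = [c for c in EVENT_COLUMNS if c not in self.events.columns]
        if missing:
            raise OmopIOError(f"event store missing column(s) {missing}")

    def domain_counts(self) -> dict[str, int]:
        return self.events["domain"].value_counts().to_dict()


class RelationshipGraph:
    """CONCEPT_RELATIONSHIP as a directed multigraph keyed by relationship_id."""

    def __init__(self, graph: nx.MultiDiGraph, unknown_endpoints: list[int] | None = None):
        self.graph = graph
        self.unknown_endpoints = unknown_endpoints or []

    @property
    def n_edges(self) -> int:
        return self.graph.number_of_edges()

    def successors(self, concept_id: int, relationship_ids) -> list[int]:
        """Concepts reachable in one hop along the given relationship kinds."""
        if concept_id not in self.graph:
            return []
        wanted = set(relationship_ids)
        return [v for _, v, key in self.graph.out_edges(concept_id, keys=True) if key in wanted]


def read_concepts(path: str | Path, sep: str = ",") -> ConceptCatalogue:
    """Read an OMOP CONCEPT table file into a catalogue keyed by concept_id.

    Raises :class:`OmopIOError` on duplicate concept ids or missing columns.
    """
    df = _read_table(path, sep=sep)
    _require_columns(df, CONCEPT_REQUIRED, path)
    return ConceptCatalogue(df)


def read_relationships(path: str | Path, concepts: ConceptCatalogue | None = None, sep: str = ",") -> RelationshipGraph:
    """Read CONCEPT_RELATIONSHIP into a directed multigraph.

    Duplicate (subject, object, relationship) triples are deduplicated with a
    warning; endpoints absent from the catalogue are collected in
    ``unknown_endpoints`` (the rows are kept).
    """
    df = _read_table(path, sep=sep)
    _require_columns(df, RELATIONSHIP_REQUIRED, path)
    df = df.astype({"concept_id_1": "int64", "concept_id_2": "int64"})
    before = len(df)
    df = df.drop_duplicates(subset=list(RELATIONSHIP_REQUIRED))
    if len(df) < before:
        warnings.warn(f"{path}: {before - len(df)} duplicate relationship triple(s) deduplicated")
    unknown: list[int] = []
    if concepts is not None:
        ids = pd.unique(pd.concat([df["concept_id_1"], df["concept_id_2"]]))
        unknown = sorted(int(i) for i in ids if i not in concepts)
        if unknown:
            warnings.warn(f"{path}: {len(unknown)} relationship endpoint(s) not in catalogue")
    g = nx.MultiDiGraph()
    for s, o, r in df[list(RELATIONSHIP_REQUIRED)].itertuples(index=False):
        g.add_edge(int(s), int(o), key=str(r))
    return RelationshipGraph(g, unknown)


def _load_domain(path, domain: str, sep: str) -> pd.DataFrame:
    df = _read_table(path, sep=sep)
    id_col = f"{domain}_id"
    concept_col = f"{domain}_concept_id"
    for alt, canonical in ((id_col, "event_id"), ("event_id", "event_id"),
                           (concept_col, "element_concept_id"), ("element_concept_id", "element_concept_id")):
        if alt in df.columns:
            df = df.rename(columns={alt: canonical})
    _require_columns(df, ("event_id", "person_id", "element_concept_id"), path)
    out = pd.DataFrame({
        "event_id": df["event_id"].astype("int64"),
        "person_id": df["person_id"].astype("int64"),
        "element_concept_id": df["element_concept_id"].astype("int64"),
        "domain": domain,
        "value_as_number": pd.to_numeric(df.get("value_as_number"), errors="coerce").astype("float64")
        if "value_as_number" in df.columns else float("nan"),
        "value_as_concept_id": df["value_as_concept_id"].fillna(NONE_VALUE_ID).astype("int64")
        if "value_as_concept_id" in df.columns else NONE_VALUE_ID,
    })
    if "src_id" in df.columns:
        out["src_id"] = df["src_id"].astype(str)
    return out


def _join_src(base: pd.DataFrame, ext_path, domain: str, sep: str, default_src: str):
    """Join src_id from an extension table keyed on the domain's event id."""
    dropped = pd.DataFrame(columns=["event_id", "src_id", "domain"])
    if ext_path is None:
        if "src_id" not in base.columns:
            base["src_id"] = default_src
        return base, dropped
    ext = _read_table(ext_path, sep=sep)
    key = next((c for c in (f"{domain}_id", "event_id") if c in ext.columns), None)
    if key is None or "src_id" not in ext.columns:
        raise OmopIOError(f"{ext_path}: extension table needs ({domain}_id|event_id, src_id)")
    ext = ext.rename(columns={key: "event_id"}).astype({"event_id": "int64"})
    known = ext["event_id"].isin(set(base["event_id"]))
    if (~known).any():
        dropped = ext.loc[~known, ["event_id", "src_id"]].assign(domain=domain)
        warnings.warn(f"{ext_path}: {len(dropped)} extension row(s) reference unknown event ids; dropped")
        ext = ext[known]
    mapping = ext.set_index("event_id")["src_id"].astype(str)
    joined = base["event_id"].map(mapping)
    if "src_id" in base.columns:
        base["src_id"] = joined.fillna(base["src_id"])
    else:
        base["src_id"] = joined.fillna(default_src)
    return base, dropped


def read_clinical_events(
    measurement_path=None,
    observation_path=None,
    measurement_ext_path=None,
    observation_ext_path=None,
    concepts: ConceptCatalogue | None = None,
    config: ProfileConfig = DEFAULT_CONFIG,
    sep: str = ",",
) -> EventStore:
    """Read MEASUREMENT and OBSERVATION rows into a unified event store.

    src_id is taken from the extension tables when provided, else from an
    inline ``src_id`` column, else set to ``config.default_src_id``.  If a
    catalogue is given, any event whose element concept does not resolve is
    a hard error.
    """
    parts, dropped_parts = [], []
    for path, ext, domain in ((measurement_path, measurement_ext_path, "measurement"),
                              (observation_path, observation_ext_path, "observation")):
        if path is None:
            continue
        base = _load_domain(path, domain, sep)
        base, dropped = _join_src(base, ext, domain, sep, config.default_src_id)
        parts.append(base)
        dropped_parts.append(dropped)
    if not parts:
        raise OmopIOError("at least one of measurement_path / observation_path is required")
    events = pd.concat(parts, ignore_index=True)[list(EVENT_COLUMNS)]
    if concepts is not None:
        unresolved = set(events["element_concept_id"]) - set(concepts.frame.index)
        if unresolved:
            raise OmopIOError(f"element concept id(s) not in catalogue: {sorted(unresolved)[:10]}")
    dropped = pd.concat(dropped_parts, ignore_index=True) if dropped_parts else pd.DataFrame()
    return EventStore(events, dropped)


def read_initiative_lookup(path: str | Path, sep: str = ",") -> dict[str, str]:
    """Read a (loinc_code, initiative) lookup; each code maps to one label."""
    df = _read_table(path, sep=sep)
    _require_columns(df, ("loinc_code", "initiative"), path)
    df["loinc_code"] = df["loinc_code"].astype(str)
    dup = df["loinc_code"][df["loinc_code"].duplicated()]
    if len(dup):
        raise OmopIOError(f"loinc_code(s) mapped to multiple initiatives: {sorted(set(dup))}")
    return dict(zip(df["loinc_code"], df["initiative"].astype(str)))
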