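"""A study bundle: one coherent set of OMOP table frames on disk or in memory.

The synthetic generator and the reference fixture both emit a
:class:`StudyBundle`; the profiling pipeline can consume one directly (no
disk round-trip) or from a directory written by :meth:`StudyBundle.write`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as omop_io
from .config import ProfileConfig, DEFAULT_CONFIG

FILENAMES = {
    "concepts": "concept.csv",
    "relationships": "concept_relationship.csv",
    "measurement": "measurement.csv",
    "observation": "observation.csv",
    "measurement_ext": "measurement_ext.csv",
    "observation_ext": "observation_ext.csv",
    "initiatives": "initiative_lookup.csv",
}


@dataclass
class StudyBundle:
    """OMOP-shaped tables for one study, as raw pandas frames."""

    concepts: pd.DataFrame
    relationships: pd.DataFrame
    measurement: pd.DataFrame
    observation: pd.DataFrame
    measurement_ext: pd.DataFrame | None = None
    observation_ext: pd.DataFrame | None = None
    initiatives: pd.DataFrame | None = None
    total_participants: int | None = None
    metadata: dict = field(default_factory=dict)

    def write(self, out_dir: str | Path) -> Path:
        """Write all tables as comma-separated UTF-8 text; returns the dir."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        for attr, fname in FILENAMES.items():
            frame = getattr(self, attr)
            if frame is not None:
                frame.to_csv(out / fname, index=False)
        meta = dict(self.metadata)
        if self.total_participants is not None:
            meta["total_participants"] = int(self.total_participants)
        (out / "bundle.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
        return out

    @classmethod
    def read(cls, in_dir: str | Path) -> "StudyBundle":
        src = Path(in_dir)
        frames = {}
        for attr, fname in FILENAMES.items():
            p = src / fname
            frames[attr] = pd.read_csv(p) if p.exists() else None
        meta_path = src / "bundle.json"
        meta = json.loads(meta_path.read_text()) if meta_path.exists() else {}
        total = meta.pop("total_participants", None)
        return cls(total_participants=total, metadata=meta, **frames)

    # -- adapters into the pipeline's validated containers -----------------

    def concept_catalogue(self) -> omop_io.ConceptCatalogue:
        return omop_io.ConceptCatalogue(self.concepts)

    def relationship_graph(self, concepts=None) -> omop_io.RelationshipGraph:
        import networkx as nx

        df = self.relationships.drop_duplicates(subset=["concept_id_1", "concept_id_2", "relationship_id"])
        g = nx.MultiDiGraph()
        for s, o, r in df[["concept_id_1", "concept_id_2", "relationship_id"]].itertuples(index=False):
            g.add_edge(int(s), int(o), key=str(r))
        return omop_io.RelationshipGraph(g)

    def event_store(self, config: ProfileConfig = DEFAULT_CONFIG) -> omop_io.EventStore:
        parts = []
        for frame, ext, domain in ((self.measurement, self.measurement_ext, "measurement"),
                                   (self.observation, self.observation_ext, "observation")):
            if frame is None or len(frame) == 0:
                continue
            base = frame.rename(columns={f"{domain}_id": "event_id", f"{domain}_concept_id": "element_concept_id"}).copy()
            base["domain"] = domain
            if "value_as_number" not in base.columns:
                base["value_as_number"] = float("nan")
            base["value_as_number"] = pd.to_numeric(base["value_as_number"], errors="coerce")
            if "value_as_concept_id" not in base.columns:
                base["value_as_concept_id"] = 0
            base["value_as_concept_id"] = base["value_as_concept_id"].fillna(0).astype("int64")
            if ext is not None:
                key = f"{domain}_id" if f"{domain}_id" in ext.columns else "event_id"
                mapping = ext.set_index(ext[key].astype("int64"))["src_id"].astype(str)
                base["src_id"] = base["event_id"].map(mapping).fillna(
                    base["src_id"] if "src_id" in base.columns else config.default_src_id)
            elif "src_id" not in base.columns:
                base["src_id"] = config.default_src_id
            parts.append(base[list(omop_io.EVENT_COLUMNS)])
        events = pd.concat(parts, ignore_index=True)
        return omop_io.EventStore(events)

    def initiative_lookup(self) -> dict[str, str]:
        if self.initiatives is None or len(self.initiatives) == 0:
            return {}
        return dict(zip(self.initiatives["loinc_code"].astype(str), self.initiatives["initiative"].astype(str)))
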