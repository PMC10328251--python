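"""Profiling configuration.

All knobs that the audit pipeline exposes live on :class:`ProfileConfig`.
Defaults mirror the conventions of the All of Us registered-tier releases:
survey questions and answers are minted in the custom ``PPI`` and
``AoU_General`` vocabularies, research-visit/CRF rows carry the source label
``PPI/PM`` (also seen spelled ``PM/PPI``), answer avoidance is expressed with
the ``PMI: Skip`` (903096) and ``I prefer not to answer`` (1177221) concepts,
and exported aggregates must combine at least 20 participants.
"""

from __future__ import annotations

import json
from pathlib import Path

import yaml
from pydantic import BaseModel, Field, field_validator

#: Sentinel concept id for "no coded value" (value_as_concept_id absent or 0).
NONE_VALUE_ID = 0
#: Vocabulary label under which the sentinel is reported.
NONE_VOCABULARY = "None"


class ProfileConfig(BaseModel):
    """Settings for one audit run.

    Parameters
    ----------
    custom_vocabularies:
        vocabulary_ids considered study-custom; elements from these are
        unique data elements (UDEs), everything else is a CDE.
    crf_src_ids:
        src_id labels attributing a data row to a CRF / research visit.
        Any other label is treated as an EHR site.
    avoidance_concept_ids:
        Value concepts that express answer avoidance.  The first entry of
        ``skip_concept_ids`` drives the narrower "skip-enabled" flag.
    min_participants:
        Small-cell suppression threshold: exported aggregate rows must
        represent at least this many distinct participants.
    crf_relationship_ids:
        relationship_ids followed upward (element -> topic -> module) when
        assigning an element to its CRF.
    max_hierarchy_depth:
        Bound on the upward traversal when looking for a module concept.
    strict_src_id:
        If True a row without src_id is an error; if False it is attributed
        to EHR and counted in diagnostics.
    """

    custom_vocabularies: frozenset[str] = frozenset({"PPI", "AoU_General"})
    crf_src_ids: frozenset[str] = frozenset({"PPI/PM", "PM/PPI"})
    skip_concept_ids: frozenset[int] = frozenset({903096})
    avoidance_concept_ids: frozenset[int] = frozenset({903096, 1177221})
    min_participants: int = Field(default=20, ge=1)
    crf_relationship_ids: tuple[str, ...] = ("Has PPI parent code", "Is a")
    topic_class: str = "Topic"
    module_class: str = "Module"
    max_hierarchy_depth: int = Field(default=5, ge=1)
    percent_decimals: int = Field(default=1, ge=0)
    table_percent_decimals: int = Field(default=2, ge=0)
    default_src_id: str = "unknown"
    strict_src_id: bool = False

    model_config = {"frozen": True}

    @field_validator("custom_vocabularies")
    @classmethod
    def _non_empty_vocab_labels(cls, v: frozenset[str]) -> frozenset[str]:
        if any(not s for s in v):
            raise ValueError("custom vocabulary labels must be non-empty")
        return v

    @classmethod
    def from_file(cls, path: str | Path) -> "ProfileConfig":
        """Load a config from a YAML or JSON file."""
        path = Path(path)
        text = path.read_text()
        data = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        return cls(**(data or {}))


DEFAULT_CONFIG = ProfileConfig()
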