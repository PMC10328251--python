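"""Rendering the audit result to exportable delimited-text reports.

Every table with a participant dimension passes through small-cell
suppression before it is written; tables without one (pure value-level or
terminology-level counts) are exempt and flagged as such in
``report_metadata.json``.  Output is deterministic: fixed sort orders
(descending event count, ties broken by ascending concept id) and fixed
file names, so re-rendering identical inputs is byte-identical.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .config import ProfileConfig, DEFAULT_CONFIG
from .pipeline import ProfileResult
from .privacy import suppress_small_cells


def _element_sort(df: pd.DataFrame, count_col: str = "event_count", id_col: str = "concept_id") -> pd.DataFrame:
    return df.sort_values([count_col, id_col], ascending=[False, True], ignore_index=True)


def render_reports(result: ProfileResult, out_dir: str | Path,
                   config: ProfileConfig | None = None) -> dict:
    """Write the report bundle; returns per-file suppression metadata."""
    config = config or result.config
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    meta: dict[str, dict] = {}

    def write(name: str, df: pd.DataFrame, participant_column: str | None):
        if participant_column is not None:
            kept, outcome = suppress_small_cells(df, config, participant_column)
            meta[name] = {"rows_in": outcome.rows_in, "rows_out": outcome.rows_out,
                          "rows_suppressed": outcome.rows_suppressed, "threshold": outcome.threshold}
        else:
            kept = df
            meta[name] = {"rows_in": len(df), "rows_out": len(df),
                          "suppression": "exempt (no participant dimension)"}
        kept.to_csv(out / name, index=False)

    elements = _element_sort(result.elements.copy())
    elements["sources"] = elements["sources"].map(lambda t: "|".join(t))
    write("elements.csv", elements, "participant_count")

    names = result.elements.set_index("concept_id")
    pairs = result.pairs.merge(
        names[["concept_name", "vocabulary_id"]].rename(columns={
            "concept_name": "element_name", "vocabulary_id": "element_vocabulary"}),
        left_on="element_concept_id", right_index=True, how="left")
    vals = result.values.set_index("value_concept_id")
    pairs["value_name"] = pairs["value_concept_id"].map(vals["concept_name"])
    pairs["value_vocabulary"] = pairs["value_concept_id"].map(vals["vocabulary_id"])
    pairs = pairs.sort_values(["element_concept_id", "count", "value_concept_id"],
                              ascending=[True, False, True], ignore_index=True)
    write("element_values.csv", pairs, "participant_count")

    write("value_dictionary.csv",
          result.values.sort_values(["total_count", "value_concept_id"],
                                    ascending=[False, True], ignore_index=True), None)
    write("initiative_counts.csv", result.summary.by_initiative, None)
    write("crf_counts.csv", result.summary.by_crf, None)
    write("vocabulary_counts.csv", result.summary.by_vocabulary, None)
    write("terminology_profile.csv", result.terminology_profile, None)

    concordance = result.concordance.copy()
    concordance["value_vocabularies"] = concordance["value_vocabularies"].map(
        lambda s: "|".join(sorted(s)))
    write("concordance.csv",
          concordance.sort_values("element_concept_id", ignore_index=True), None)

    crossover = result.crossover.merge(
        names[["concept_name", "vocabulary_id", "concept_code", "event_count",
               "participant_count", "participant_pct"]],
        left_on="element_concept_id", right_index=True, how="left")
    crossover = crossover.sort_values(["event_count", "element_concept_id"],
                                      ascending=[False, True], ignore_index=True)
    write("crossover.csv", crossover, "participant_count")

    axes = result.axes.cells.copy()
    write("axes.csv", axes, None)

    narrative = {
        "total_participants": result.total_participants,
        "total_elements": result.summary.total_elements,
        "by_origin": result.summary.by_origin,
        "by_data_type": result.summary.by_data_type,
        "initiative_cdes": int(result.elements["initiative"].notna().sum()),
        "distinct_values": int(len(result.values)),
        "element_value_combinations": int(len(result.pairs)),
        "skip_enabled_elements": result.avoidance.n_skip_enabled,
        "skip_enabled_pct": result.avoidance.pct_skip_enabled,
        "avoidance_enabled_elements": result.avoidance.n_avoidance_enabled,
        "avoidance_enabled_pct": result.avoidance.pct_avoidance_enabled,
        "crossover_elements": int(len(result.crossover)),
        "ude_count_outside_axes": result.axes.ude_count,
        "concordance": result.concordance_summary,
    }
    (out / "narrative_summary.json").write_text(json.dumps(narrative, indent=2, sort_keys=True))
    (out / "report_metadata.json").write_text(json.dumps(meta, indent=2, sort_keys=True))
    return meta
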