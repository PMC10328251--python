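"""Permissible-value dictionary construction.

For categorical elements the audit descends one level below the element:
every distinct (element, value) pair observed in the data is an
*element-value combination*, identified by value_concept_id (the same display
name may exist in two terminologies, so identity is by concept id, never by
name).  Rows with no coded value are tallied under the NONE sentinel
(concept id 0, vocabulary "None").  On top of the pair table sit: a value
dictionary (per distinct value: how many elements use it, how often), the
answer-avoidance report ('PMI: Skip' / 'I prefer not to answer'), a
per-terminology value profile, and the element/value terminology concordance.

Numeric elements are out of scope for the value dictionary; any coded rows
they carry are tallied in a separate diagnostics table.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from ._util import round_half_up
from .config import ProfileConfig, DEFAULT_CONFIG, NONE_VALUE_ID
from .io import ConceptCatalogue, EventStore


def build_element_value_table(
    events: EventStore,
    concepts: ConceptCatalogue,
    element_records: pd.DataFrame,
    config: ProfileConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """One row per distinct (element, value) pair over categorical elements.

    ``pct_of_element`` is the pair's share of the element's total rows
    (including avoidance and NONE rows), rounded half-up to
    ``config.percent_decimals``.  Also computes distinct participants per
    pair so small-cell suppression can act on this table.
    """
    cat_ids = set(element_records.loc[element_records["data_type"] == "categorical", "concept_id"])
    ev = events.events
    ev = ev[ev["element_concept_id"].isin(cat_ids)]
    if len(ev) == 0:
        return pd.DataFrame(columns=["element_concept_id", "value_concept_id", "count",
                                     "participant_count", "pct_of_element"])
    pairs = (ev.groupby(["element_concept_id", "value_as_concept_id"], sort=True)
             .agg(count=("event_id", "size"), participant_count=("person_id", "nunique"))
             .reset_index()
             .rename(columns={"value_as_concept_id": "value_concept_id"}))
    totals = pairs.groupby("element_concept_id")["count"].transform("sum")
    pairs["pct_of_element"] = round_half_up(pairs["count"] / totals * 100.0, config.percent_decimals)
    return pairs


def numeric_element_coded_rows(events: EventStore, element_records: pd.DataFrame) -> pd.DataFrame:
    """Diagnostics: coded values observed on numeric elements."""
    num_ids = set(element_records.loc[element_records["data_type"] == "numeric", "concept_id"])
    ev = events.events
    ev = ev[ev["element_concept_id"].isin(num_ids) & (ev["value_as_concept_id"] != NONE_VALUE_ID)]
    return (ev.groupby(["element_concept_id", "value_as_concept_id"]).size()
            .rename("count").reset_index()
            .rename(columns={"value_as_concept_id": "value_concept_id"}))


def build_value_dictionary(
    pairs: pd.DataFrame,
    concepts: ConceptCatalogue,
    config: ProfileConfig = DEFAULT_CONFIG,
) -> pd.DataFrame:
    """One row per distinct value concept used across categorical elements.

    ``standardized`` follows the element-origin rule: the value's vocabulary
    is not one of the study-custom vocabularies.
    """
    if len(pairs) == 0:
        return pd.DataFrame(columns=["value_concept_id", "concept_name", "vocabulary_id",
                                     "n_elements", "total_count", "standardized"])
    vals = (pairs.groupby("value_concept_id")
            .agg(n_elements=("element_concept_id", "nunique"), total_count=("count", "sum"))
            .reset_index())
    vals["concept_name"] = concepts.lookup(vals["value_concept_id"], "concept_name").to_numpy()
    vals["vocabulary_id"] = concepts.lookup(vals["value_concept_id"], "vocabulary_id").to_numpy()
    vals["standardized"] = ~vals["vocabulary_id"].isin(config.custom_vocabularies)
    return vals[["value_concept_id", "concept_name", "vocabulary_id", "n_elements", "total_count", "standardized"]]


@dataclass
class AvoidanceReport:
    """How often answering can be avoided, and how often it is."""

    flags: pd.DataFrame            # element_concept_id, skip_enabled, avoidance_enabled
    n_elements: int
    n_skip_enabled: int
    pct_skip_enabled: float
    n_avoidance_enabled: int
    pct_avoidance_enabled: float
    usage: pd.DataFrame            # concept_id, rows, n_elements (per avoidance concept)


def detect_answer_avoidance(
    pairs: pd.DataFrame,
    config: ProfileConfig = DEFAULT_CONFIG,
    total_elements: int | None = None,
) -> AvoidanceReport:
    """Flag elements offering a skip / prefer-not-to-answer value.

    ``skip_enabled`` uses ``config.skip_concept_ids`` (the study's custom
    skip concept); ``avoidance_enabled`` uses the wider
    ``config.avoidance_concept_ids``.  Percentages are over
    ``total_elements`` when given (so numeric elements without pairs count
    in the denominator), else over the elements present in the pair table.
    """
    elements = pairs["element_concept_id"].drop_duplicates().sort_values(ignore_index=True)
    skip = pairs.loc[pairs["value_concept_id"].isin(config.skip_concept_ids), "element_concept_id"].unique()
    avoid = pairs.loc[pairs["value_concept_id"].isin(config.avoidance_concept_ids), "element_concept_id"].unique()
    flags = pd.DataFrame({"element_concept_id": elements})
    flags["skip_enabled"] = flags["element_concept_id"].isin(set(skip))
    flags["avoidance_enabled"] = flags["element_concept_id"].isin(set(avoid))
    denom = total_elements if total_elements else len(elements)
    usage = (pairs[pairs["value_concept_id"].isin(config.avoidance_concept_ids)]
             .groupby("value_concept_id")
             .agg(rows=("count", "sum"), n_elements=("element_concept_id", "nunique"))
             .reset_index().rename(columns={"value_concept_id": "concept_id"}))
    n_skip, n_avoid = int(flags["skip_enabled"].sum()), int(flags["avoidance_enabled"].sum())
    return AvoidanceReport(
        flags=flags,
        n_elements=denom,
        n_skip_enabled=n_skip,
        pct_skip_enabled=round_half_up(n_skip / denom * 100.0, config.percent_decimals) if denom else 0.0,
        n_avoidance_enabled=n_avoid,
        pct_avoidance_enabled=round_half_up(n_avoid / denom * 100.0, config.percent_decimals) if denom else 0.0,
        usage=usage,
    )


def value_terminology_profile(
    values: pd.DataFrame,
    pairs: pd.DataFrame,
    concepts: ConceptCatalogue,
    config: ProfileConfig = DEFAULT_CONFIG,
    total_elements: int | None = None,
) -> pd.DataFrame:
    """Per value terminology: distinct values and elements touching it.

    An element counts once per vocabulary it draws at least one value from;
    the element percentage is over ``total_elements`` when given (all
    elements in the dictionary), else over elements present in the pairs.
    """
    if len(values) == 0:
        return pd.DataFrame(columns=["vocabulary_id", "distinct_values", "pct_of_values",
                                     "n_elements", "pct_of_elements"])
    by_vocab = (values.groupby("vocabulary_id").size().rename("distinct_values").reset_index())
    total_vals = int(by_vocab["distinct_values"].sum())
    by_vocab["pct_of_values"] = round_half_up(
        by_vocab["distinct_values"] / total_vals * 100.0, config.table_percent_decimals)
    pv = pairs.copy()
    pv["vocabulary_id"] = concepts.lookup(pv["value_concept_id"], "vocabulary_id").to_numpy()
    elems = (pv.groupby("vocabulary_id")["element_concept_id"].nunique().rename("n_elements").reset_index())
    denom = total_elements if total_elements else pairs["element_concept_id"].nunique()
    out = by_vocab.merge(elems, on="vocabulary_id", how="left").fillna({"n_elements": 0})
    out["n_elements"] = out["n_elements"].astype(int)
    out["pct_of_elements"] = round_half_up(out["n_elements"] / denom * 100.0, config.table_percent_decimals)
    return out.sort_values(["distinct_values", "vocabulary_id"], ascending=[False, True], ignore_index=True)


def element_value_concordance(
    element_records: pd.DataFrame,
    pairs: pd.DataFrame,
    concepts: ConceptCatalogue,
    config: ProfileConfig = DEFAULT_CONFIG,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Compare each categorical element's terminology with its values'.

    Every categorical element falls in exactly one class:
    ``same-terminology-only`` (all values share the element's vocabulary),
    ``different-terminology-only`` (none does) or ``mixed``.  The summary
    additionally counts UDEs that draw on standardized values and CDEs that
    needed at least one custom value.
    """
    pv = pairs.copy()
    pv["value_vocab"] = concepts.lookup(pv["value_concept_id"], "vocabulary_id").to_numpy()
    vocab_sets = pv.groupby("element_concept_id")["value_vocab"].agg(lambda s: frozenset(s))
    cat = element_records[element_records["data_type"] == "categorical"]
    recs = cat[["concept_id", "vocabulary_id", "origin_class"]].rename(
        columns={"concept_id": "element_concept_id", "vocabulary_id": "element_vocab"}).copy()
    recs["value_vocabularies"] = recs["element_concept_id"].map(vocab_sets)
    recs = recs.dropna(subset=["value_vocabularies"])

    def classify(row) -> str:
        vs, ev = row["value_vocabularies"], row["element_vocab"]
        if vs == {ev}:
            return "same-terminology-only"
        return "different-terminology-only" if ev not in vs else "mixed"

    recs["concordance_class"] = recs.apply(classify, axis=1)
    custom = config.custom_vocabularies
    has_std = recs["value_vocabularies"].map(lambda vs: any(v not in custom for v in vs))
    only_std = recs["value_vocabularies"].map(lambda vs: all(v not in custom for v in vs))
    only_custom = recs["value_vocabularies"].map(lambda vs: all(v in custom for v in vs))
    has_custom = recs["value_vocabularies"].map(lambda vs: any(v in custom for v in vs))
    is_ude = recs["origin_class"] == "UDE"
    summary = {
        "same-terminology-only": int((recs["concordance_class"] == "same-terminology-only").sum()),
        "different-terminology-only": int((recs["concordance_class"] == "different-terminology-only").sum()),
        "mixed": int((recs["concordance_class"] == "mixed").sum()),
        "udes_with_standardized_values": int((is_ude & has_std).sum()),
        "udes_only_standardized_values": int((is_ude & only_std).sum()),
        "udes_only_custom_values": int((is_ude & only_custom).sum()),
        "cdes_with_custom_values": int((~is_ude & has_custom).sum()),
    }
    cols = ["element_concept_id", "element_vocab", "origin_class", "concordance_class", "value_vocabularies"]
    return recs[cols].reset_index(drop=True), summary
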