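import pandas as pd
import pytest

import cdeaudit as ca
from .conftest import make_events


def profile_pairs(store, concepts):
    records = ca.build_element_dictionary(store, concepts)
    return records, ca.build_element_value_table(store, concepts, records)


class TestElementValueTable:
    def test_yes_no_shares(self, tiny_concepts):
        store = make_events([
            (1, 1, 40771103, None, 100, "PPI/PM"),
            (2, 2, 40771103, None, 100, "PPI/PM"),
            (3, 3, 40771103, None, 100, "PPI/PM"),
            (4, 4, 40771103, None, 101, "PPI/PM"),
        ])
        _, pairs = profile_pairs(store, tiny_concepts)
        by_val = pairs.set_index("value_concept_id")
        assert by_val.at[100, "count"] == 3 and by_val.at[100, "pct_of_element"] == 75.0
        assert by_val.at[101, "count"] == 1 and by_val.at[101, "pct_of_element"] == 25.0

    def test_uncoded_rows_counted_under_none_sentinel(self, tiny_concepts):
        store = make_events([
            (1, 1, 40771103, None, 100, "PPI/PM"),
            (2, 2, 40771103, None, None, "PPI/PM"),
        ])
        _, pairs = profile_pairs(store, tiny_concepts)
        assert set(pairs["value_concept_id"]) == {100, ca.NONE_VALUE_ID}

    def test_numeric_elements_excluded_from_pairs(self, tiny_concepts):
        store = make_events([
            (1, 1, 3027018, 72.0, None, "PPI/PM"),
            (2, 2, 40771103, None, 100, "PPI/PM"),
        ])
        _, pairs = profile_pairs(store, tiny_concepts)
        assert set(pairs["element_concept_id"]) == {40771103}

    def test_counts_equal_brute_force_recount(self, small_study, small_result):
        bundle, _ = small_study
        ev = bundle.event_store().events
        cat = set(small_result.elements.loc[
            small_result.elements["data_type"] == "categorical", "concept_id"])
        brute = (ev[ev["element_concept_id"].isin(cat)]
                 .groupby(["element_concept_id", "value_as_concept_id"]).size())
        got = small_result.pairs.set_index(["element_concept_id", "value_concept_id"])["count"]
        assert got.sort_index().equals(brute.sort_index().rename("count"))

    def test_pct_of_element_sums_to_one_hundred_within_rounding(self, small_result):
        per_elem = small_result.pairs.groupby("element_concept_id").agg(
            total_pct=("pct_of_element", "sum"), n=("value_concept_id", "size"))
        tol = 0.1 * per_elem["n"]
        assert ((per_elem["total_pct"] - 100.0).abs() <= tol).all()

    def test_event_count_conserved_into_pairs(self, small_result):
        cat = small_result.elements[small_result.elements["data_type"] == "categorical"]
        pair_totals = small_result.pairs.groupby("element_concept_id")["count"].sum()
        assert (cat.set_index("concept_id")["event_count"].sort_index()
                == pair_totals.sort_index()).all()


class TestValueDictionary:
    def test_value_shared_by_two_elements(self, tiny_concepts):
        store = make_events([
            (1, 1, 40771103, None, 100, "PPI/PM"),
            (2, 2, 3027018, None, 100, "PPI/PM"),
        ])
        _, pairs = profile_pairs(store, tiny_concepts)
        vals = ca.build_value_dictionary(pairs, tiny_concepts)
        assert vals.set_index("value_concept_id").at[100, "n_elements"] == 2

    def test_total_count_conservation(self, small_result):
        assert small_result.values["total_count"].sum() == small_result.pairs["count"].sum()

    def test_standardized_flag_follows_custom_vocabularies(self, small_result):
        v = small_result.values
        assert (v["standardized"] == ~v["vocabulary_id"].isin({"PPI", "AoU_General"})).all()


class TestAnswerAvoidance:
    def test_skip_value_flags_element(self, tiny_concepts):
        store = make_events([
            (1, 1, 40771103, None, 903096, "PPI/PM"),
            (2, 2, 40771103, None, 100, "PPI/PM"),
            (3, 3, 3027018, None, 100, "PPI/PM"),
        ])
        _, pairs = profile_pairs(store, tiny_concepts)
        report = ca.detect_answer_avoidance(pairs)
        flags = report.flags.set_index("element_concept_id")
        assert bool(flags.at[40771103, "skip_enabled"])
        assert not bool(flags.at[3027018, "avoidance_enabled"])
        assert report.n_skip_enabled == 1

    def test_avoidance_usage_rows_counted(self, tiny_concepts):
        store = make_events([(i, i, 40771103, None, 903096, "PPI/PM") for i in range(3)]
                            + [(9, 9, 40771103, None, 100, "PPI/PM")])
        _, pairs = profile_pairs(store, tiny_concepts)
        usage = ca.detect_answer_avoidance(pairs).usage.set_index("concept_id")
        assert usage.at[903096, "rows"] == 3


class TestTerminologyProfile:
    def test_single_vocabulary_is_one_hundred_percent(self, tiny_concepts):
        store = make_events([(1, 1, 40771103, None, 100, "PPI/PM")])
        _, pairs = profile_pairs(store, tiny_concepts)
        vals = ca.build_value_dictionary(pairs, tiny_concepts)
        prof = ca.value_terminology_profile(vals, pairs, tiny_concepts)
        assert len(prof) == 1 and prof["pct_of_values"].iloc[0] == 100.0

    def test_element_counted_once_per_vocabulary(self, tiny_concepts):
        store = make_events([
            (1, 1, 40771103, None, 100, "PPI/PM"),   # LOINC value
            (2, 2, 40771103, None, 101, "PPI/PM"),   # SNOMED value
            (3, 3, 40771103, None, 903096, "PPI/PM"),  # PPI value
        ])
        _, pairs = profile_pairs(store, tiny_concepts)
        vals = ca.build_value_dictionary(pairs, tiny_concepts)
        prof = ca.value_terminology_profile(vals, pairs, tiny_concepts).set_index("vocabulary_id")
        assert (prof["n_elements"] == 1).all()


class TestConcordance:
    def build(self, rows, concepts):
        store = make_events(rows)
        records, pairs = profile_pairs(store, concepts)
        return ca.element_value_concordance(records, pairs, concepts)

    def test_ude_with_all_standard_values_is_different_terminology_only(self):
        frame = pd.DataFrame([
            {"concept_id": 1, "concept_name": "Cancer age question", "vocabulary_id": "PPI",
             "concept_code": "", "concept_class_id": "Question", "standard_concept": "S"},
            {"concept_id": 10, "concept_name": "Adult", "vocabulary_id": "LOINC",
             "concept_code": "LA1", "concept_class_id": "Answer", "standard_concept": "S"},
            {"concept_id": 11, "concept_name": "75+ years", "vocabulary_id": "LOINC",
             "concept_code": "LA2", "concept_class_id": "Answer", "standard_concept": "S"},
        ])
        cat = ca.ConceptCatalogue(frame)
        recs, summary = self.build([(1, 1, 1, None, 10, "PPI/PM"), (2, 2, 1, None, 11, "PPI/PM")], cat)
        assert recs["concordance_class"].iloc[0] == "different-terminology-only"
        assert summary["udes_only_standardized_values"] == 1

    def test_cde_with_one_custom_value_is_mixed(self):
        frame = pd.DataFrame([
            {"concept_id": 1, "concept_name": "Household income", "vocabulary_id": "LOINC",
             "concept_code": "77244-2", "concept_class_id": "Question", "standard_concept": "S"},
            {"concept_id": 10, "concept_name": "Annual income 50k-75k", "vocabulary_id": "PPI",
             "concept_code": "", "concept_class_id": "Answer", "standard_concept": "S"},
            {"concept_id": 11, "concept_name": "Yes", "vocabulary_id": "LOINC",
             "concept_code": "LA33-6", "concept_class_id": "Answer", "standard_concept": "S"},
        ])
        cat = ca.ConceptCatalogue(frame)
        recs, summary = self.build([(1, 1, 1, None, 10, "PPI/PM"), (2, 2, 1, None, 11, "PPI/PM")], cat)
        assert recs["concordance_class"].iloc[0] == "mixed"
        assert summary["cdes_with_custom_values"] == 1

    def test_sole_value_sharing_vocabulary_is_same_terminology_only(self, tiny_concepts):
        recs, _ = self.build([(1, 1, 40771103, None, 100, "PPI/PM")], tiny_concepts)
        assert recs["concordance_class"].iloc[0] == "same-terminology-only"

    def test_classes_partition_categorical_elements(self, small_result):
        n_cat = int((small_result.elements["data_type"] == "categorical").sum())
        s = small_result.concordance_summary
        assert s["same-terminology-only"] + s["different-terminology-only"] + s["mixed"] == n_cat
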