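import networkx as nx
import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cdeaudit as ca
from cdeaudit.elements import _traverse
from .conftest import make_events


class TestBuildElementDictionary:
    def test_counts_events_and_distinct_participants(self, tiny_concepts):
        store = make_events([
            (1, 1, 3027018, 72.0, None, "PPI/PM"),
            (2, 1, 3027018, 70.0, None, "PPI/PM"),
            (3, 2, 3027018, 68.0, None, "PPI/PM"),
            (4, 1, 40771103, None, 100, "PPI/PM"),
        ])
        d = ca.build_element_dictionary(store, tiny_concepts).set_index("concept_id")
        assert d.at[3027018, "event_count"] == 3
        assert d.at[3027018, "participant_count"] == 2
        assert d.at[40771103, "event_count"] == 1
        assert d.at[40771103, "participant_count"] == 1

    def test_supplied_total_overrides_inferred_denominator(self, tiny_concepts):
        store = make_events([(1, 1, 3027018, 72.0, None, "PPI/PM")])
        d = ca.build_element_dictionary(store, tiny_concepts, total_participants=20)
        assert d["participant_pct"].iloc[0] == 5.0

    def test_empty_store_gives_empty_dictionary(self, tiny_concepts):
        store = make_events([])
        assert len(ca.build_element_dictionary(store, tiny_concepts)) == 0

    def test_adding_new_person_never_decreases_participant_count(self, tiny_concepts):
        rows = [(i, i % 3, 3027018, 72.0, None, "PPI/PM") for i in range(6)]
        before = ca.build_element_dictionary(make_events(rows), tiny_concepts)
        after = ca.build_element_dictionary(make_events(rows + [(9, 7, 3027018, 70.0, None, "PPI/PM")]),
                                            tiny_concepts)
        assert after["participant_count"].iloc[0] >= before["participant_count"].iloc[0]
        assert after["participant_pct"].iloc[0] >= before["participant_pct"].iloc[0]


class TestOriginAndType:
    @pytest.mark.parametrize("vocab,expected", [
        ("LOINC", "CDE"), ("SNOMED", "CDE"), ("UCUM", "CDE"),
        ("PPI", "UDE"), ("AoU_General", "UDE"),
    ])
    def test_origin_follows_vocabulary(self, vocab, expected):
        assert ca.classify_element_origin(vocab) == expected

    def test_majority_numeric(self):
        assert ca.classify_data_type([1.0] * 60 + [None] * 40) == "numeric"

    def test_exactly_half_numeric_is_categorical(self):
        assert ca.classify_data_type([1.0] * 50 + [None] * 50) == "categorical"

    def test_empty_sequence_is_an_error(self):
        with pytest.raises(ValueError):
            ca.classify_data_type([])

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.one_of(st.none(), st.floats(allow_nan=False, allow_infinity=False)),
                    min_size=1, max_size=30))
    def test_matches_brute_force_count(self, rows):
        brute = "numeric" if sum(v is not None for v in rows) / len(rows) > 0.5 else "categorical"
        assert ca.classify_data_type(rows) == brute


class TestInitiativeMapping:
    LOOKUP = {"63513-6": "PhenX", "61579-9": "PROMIS"}

    @pytest.mark.parametrize("vocab,code,expected", [
        ("LOINC", "63513-6", "PhenX"),
        ("LOINC", "61579-9", "PROMIS"),
        ("LOINC", "0000-0", None),
        ("PPI", "63513-6", None),      # UDEs never receive an initiative
        ("SNOMED", "63513-6", None),   # only LOINC codes join the lookup
    ])
    def test_lookup_by_loinc_code(self, vocab, code, expected):
        assert ca.map_initiative(vocab, code, self.LOOKUP) == expected


class TestCrfAssignment:
    def graph(self, edges):
        g = nx.MultiDiGraph()
        for s, o in edges:
            g.add_edge(s, o, key="Has PPI parent code")
        return ca.RelationshipGraph(g)

    def test_element_to_topic_to_module(self, tiny_concepts):
        g = self.graph([(40771103, 200), (200, 300)])
        assert ca.assign_crf(40771103, g, tiny_concepts) == "Lifestyle"
        assert _traverse(40771103, g, tiny_concepts, ca.DEFAULT_CONFIG)[1] == "Alcohol"

    def test_element_without_hierarchy_gets_no_crf(self, tiny_concepts):
        assert ca.assign_crf(3027018, self.graph([]), tiny_concepts) == ca.NO_CRF

    def test_module_beyond_depth_bound_is_unreachable(self, tiny_concepts):
        cfg = ca.ProfileConfig(max_hierarchy_depth=1)
        g = self.graph([(40771103, 200), (200, 300)])
        assert ca.assign_crf(40771103, g, tiny_concepts, cfg) == ca.NO_CRF

    def test_cycle_is_an_error(self, tiny_concepts):
        g = self.graph([(40771103, 200), (200, 40771103)])
        with pytest.raises(ca.HierarchyCycleError):
            ca.assign_crf(40771103, g, tiny_concepts)

    def test_module_tie_breaks_lexicographically_and_flags_ambiguity(self):
        frame = pd.DataFrame([
            {"concept_id": 1, "concept_name": "q", "vocabulary_id": "PPI", "concept_code": "",
             "concept_class_id": "Question", "standard_concept": "S"},
            {"concept_id": 2, "concept_name": "Zed", "vocabulary_id": "PPI", "concept_code": "",
             "concept_class_id": "Module", "standard_concept": "S"},
            {"concept_id": 3, "concept_name": "Alpha", "vocabulary_id": "PPI", "concept_code": "",
             "concept_class_id": "Module", "standard_concept": "S"},
        ])
        cat = ca.ConceptCatalogue(frame)
        g = self.graph([(1, 2), (1, 3)])
        crf, _topic, ambiguous = _traverse(1, g, cat, ca.DEFAULT_CONFIG)
        assert crf == "Alpha" and ambiguous


class TestSummary:
    def test_single_element_dictionary_is_one_hundred_percent(self, tiny_concepts):
        store = make_events([(1, 1, 3027018, 72.0, None, "PPI/PM")])
        s = ca.summarize_dictionary(ca.build_element_dictionary(store, tiny_concepts))
        assert s.total_elements == 1
        assert s.by_vocabulary["pct"].iloc[0] == 100.0

    def test_partition_invariants_on_synthetic_study(self, small_result):
        s = small_result.summary
        assert s.by_vocabulary["elements"].sum() == s.total_elements
        assert s.by_origin.get("CDE", 0) + s.by_origin.get("UDE", 0) == s.total_elements
        assert s.by_crf["elements"].sum() == s.total_elements
        assert (s.by_crf["udes"] + s.by_crf["cdes"]).equals(s.by_crf["elements"])

    def test_per_element_counts_equal_naive_recount(self, small_study, small_result):
        bundle, _ = small_study
        ev = bundle.event_store().events
        recount = ev.groupby("element_concept_id").agg(
            n=("event_id", "size"), p=("person_id", "nunique"))
        d = small_result.elements.set_index("concept_id")
        assert (d["event_count"] == recount["n"]).all()
        assert (d["participant_count"] == recount["p"]).all()
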