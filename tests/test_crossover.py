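import pytest

import cdeaudit as ca
from .conftest import make_events


class TestAttributeSource:
    @pytest.mark.parametrize("src,expected", [
        ("PPI/PM", "CRF"), ("PM/PPI", "CRF"), ("site_17", "EHR"), ("EHR site 101", "EHR"),
    ])
    def test_label_attribution(self, src, expected):
        assert ca.attribute_source(src) == expected

    def test_missing_src_is_ehr_in_lenient_mode_error_in_strict(self):
        assert ca.attribute_source(None) == "EHR"
        with pytest.raises(ValueError):
            ca.attribute_source(None, ca.ProfileConfig(strict_src_id=True))


class TestCrossoverElements:
    def test_single_source_element_absent_from_list(self, tiny_concepts):
        store = make_events([(1, 1, 40771103, None, 100, "PPI/PM"),
                             (2, 2, 3027018, 70.0, None, "site_1")])
        assert len(ca.find_crossover_elements(store)) == 0

    def test_pct_from_crf(self, tiny_concepts):
        rows = [(i, i, 40771103, None, 100, "PPI/PM") for i in range(99)]
        rows.append((99, 99, 40771103, None, 100, "site_1"))
        xo = ca.find_crossover_elements(make_events(rows))
        assert len(xo) == 1
        assert xo["pct_from_crf"].iloc[0] == 99.0

    def test_source_split_conserves_event_counts(self, small_result):
        d = small_result.elements.set_index("concept_id")["event_count"]
        src = small_result.source_counts.set_index("element_concept_id")
        total = (src["crf_event_count"] + src["ehr_event_count"]).sort_index()
        assert total.equals(d.sort_index().rename(None))

    def test_planted_source_fractions_recovered(self, small_study, small_result):
        _, truth = small_study
        merged = small_result.source_counts.merge(
            truth.per_element, left_on="element_concept_id", right_on="concept_id")
        assert (merged["crf_event_count"] == merged["crf_rows"]).all()
        assert (merged["ehr_event_count"] == merged["ehr_rows"]).all()


class TestAxes:
    def test_no_crossover_puts_all_cdes_in_research_cell(self, small_result):
        axes = ca.classify_axes(small_result.elements, small_result.crossover.iloc[0:0])
        n_cde = int((small_result.elements["origin_class"] == "CDE").sum())
        assert axes.cell("O2-research", "T1-ingested") == n_cde
        assert axes.cell("O1-healthcare", "T1-ingested") == 0

    def test_cells_sum_to_cde_total_and_udes_stay_outside(self, small_result):
        axes = small_result.axes
        n_cde = int((small_result.elements["origin_class"] == "CDE").sum())
        assert axes.cells["element_count"].sum() == n_cde
        assert axes.ude_count == int((small_result.elements["origin_class"] == "UDE").sum())

    def test_supplied_healthcare_universe_drives_o1(self, small_result):
        cdes = small_result.elements[small_result.elements["origin_class"] == "CDE"]
        universe = set(cdes["concept_id"].head(2)) | {424242}
        axes = ca.classify_axes(small_result.elements, small_result.crossover, universe)
        assert axes.cell("O1-healthcare", "T1-ingested") == 2
        assert axes.healthcare_total == 3
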