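import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

import cdeaudit as ca
from cdeaudit.synthetic import largest_remainder


class TestLargestRemainder:
    def test_exact_allocation_example(self):
        assert largest_remainder({"a": 0.5, "b": 0.3, "c": 0.2}, 10) == {"a": 5, "b": 3, "c": 2}

    @settings(max_examples=100, derandomize=True)
    @given(st.lists(st.floats(min_value=0.01, max_value=1.0), min_size=1, max_size=6),
           st.integers(min_value=0, max_value=500))
    def test_allocation_sums_to_total(self, weights, total):
        s = sum(weights)
        props = {f"k{i}": w / s for i, w in enumerate(weights)}
        alloc = largest_remainder(props, total)
        assert sum(alloc.values()) == total
        assert all(v >= 0 for v in alloc.values())


class TestGeneratorDeterminism:
    def test_same_seed_same_bundle(self):
        cfg = ca.GeneratorConfig(seed=5, n_elements=30, n_participants=120)
        b1, t1 = ca.generate_study(cfg)
        b2, t2 = ca.generate_study(cfg)
        for attr in ("concepts", "relationships", "measurement", "observation",
                     "measurement_ext", "observation_ext", "initiatives"):
            pd.testing.assert_frame_equal(getattr(b1, attr), getattr(b2, attr))
        assert t1.globals == t2.globals

    def test_seed_change_preserves_category_counts(self):
        base = dict(n_elements=40, n_participants=160)
        _, t1 = ca.generate_study(ca.GeneratorConfig(seed=1, **base))
        _, t2 = ca.generate_study(ca.GeneratorConfig(seed=2, **base))
        keys = ("cde_count", "ude_count", "numeric_count", "categorical_count",
                "skip_enabled_count", "crossover_count")
        assert {k: t1.globals[k] for k in keys} == {k: t2.globals[k] for k in keys}
        assert sorted(t1.globals["per_crf_counts"].values()) == sorted(t2.globals["per_crf_counts"].values())


class TestPlantedStructure:
    def test_pure_custom_mixture_yields_only_udes(self):
        cfg = ca.GeneratorConfig(seed=3, n_elements=10, n_participants=60,
                                 vocabulary_mixture={"PPI": 1.0})
        _, truth = ca.generate_study(cfg)
        assert truth.globals["ude_count"] == 10 and truth.globals["cde_count"] == 0

    def test_zero_crossover_fraction_leaves_crossover_empty(self):
        cfg = ca.GeneratorConfig(seed=3, n_elements=20, n_participants=80, crossover_fraction=0.0)
        bundle, truth = ca.generate_study(cfg)
        assert truth.globals["crossover_count"] == 0
        result = ca.profile_study(bundle)
        assert len(result.crossover) == 0

    def test_infeasible_answer_sets_rejected_before_writing(self):
        with pytest.raises(ValueError):
            ca.GeneratorConfig(values_per_element=(0, 4))
        with pytest.raises(ValueError):
            ca.GeneratorConfig(rows_per_element=4, values_per_element=(2, 8))
        with pytest.raises(ValueError):
            ca.GeneratorConfig(vocabulary_mixture={"LOINC": 0.5, "PPI": 0.4})

    def test_every_planted_value_is_observed(self, small_study):
        bundle, truth = small_study
        observed = bundle.event_store().events.groupby("element_concept_id")[
            "value_as_concept_id"].nunique()
        cat = truth.per_element[truth.per_element["data_type"] == "categorical"]
        assert (observed.reindex(cat["concept_id"]).to_numpy() == cat["n_values"].to_numpy()).all()


class TestPipelineRecovery:
    def test_ground_truth_recovered_exactly(self, small_study, small_result):
        _, truth = small_study
        r = small_result
        assert r.summary.by_origin.get("CDE", 0) == truth.globals["cde_count"]
        assert r.summary.by_origin.get("UDE", 0) == truth.globals["ude_count"]
        assert r.summary.by_data_type.get("numeric", 0) == truth.globals["numeric_count"]
        assert r.avoidance.n_skip_enabled == truth.globals["skip_enabled_count"]
        assert len(r.crossover) == truth.globals["crossover_count"]
        assert r.elements.groupby("crf").size().to_dict() == truth.globals["per_crf_counts"]
        merged = r.elements.merge(truth.per_element, on="concept_id", suffixes=("", "_t"))
        assert len(merged) == truth.globals["n_elements"]
        for col in ("vocabulary_id", "origin_class", "data_type", "crf"):
            assert (merged[col] == merged[f"{col}_t"]).all(), col
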