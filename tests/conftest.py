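import pandas as pd
import pytest

import cdeaudit as ca


@pytest.fixture(scope="session")
def reference_bundle():
    return ca.make_reference_study()


@pytest.fixture(scope="session")
def reference_result(reference_bundle):
    """Full audit over the reference bundle (built once per session)."""
    return ca.profile_study(reference_bundle)


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study plus its ground-truth manifest."""
    cfg = ca.GeneratorConfig(seed=11, n_elements=50, n_participants=250)
    bundle, truth = ca.generate_study(cfg)
    return bundle, truth


@pytest.fixture(scope="session")
def small_result(small_study):
    bundle, _ = small_study
    return ca.profile_study(bundle)


@pytest.fixture
def tiny_concepts():
    """A hand-built catalogue: two questions, answers, a topic and a module."""
    frame = pd.DataFrame([
        {"concept_id": 3027018, "concept_name": "Heart rate", "vocabulary_id": "LOINC",
         "concept_code": "8867-4", "concept_class_id": "Question", "standard_concept": "S"},
        {"concept_id": 903096, "concept_name": "PMI: Skip", "vocabulary_id": "PPI",
         "concept_code": "PMI_Skip", "concept_class_id": "Answer", "standard_concept": "S"},
        {"concept_id": 40771103, "concept_name": "How often do you have a drink containing alcohol",
         "vocabulary_id": "LOINC", "concept_code": "68518-0", "concept_class_id": "Question",
         "standard_concept": "S"},
        {"concept_id": 100, "concept_name": "Yes", "vocabulary_id": "LOINC",
         "concept_code": "LA33-6", "concept_class_id": "Answer", "standard_concept": "S"},
        {"concept_id": 101, "concept_name": "No", "vocabulary_id": "SNOMED",
         "concept_code": "2667000", "concept_class_id": "Answer", "standard_concept": "S"},
        {"concept_id": 200, "concept_name": "Alcohol", "vocabulary_id": "PPI",
         "concept_code": "T-alc", "concept_class_id": "Topic", "standard_concept": "S"},
        {"concept_id": 300, "concept_name": "Lifestyle", "vocabulary_id": "PPI",
         "concept_code": "M-life", "concept_class_id": "Module", "standard_concept": "S"},
    ])
    return ca.ConceptCatalogue(frame)


def make_events(rows):
    """Build an EventStore from (event_id, person, element, vnum, vconc, src) tuples."""
    df = pd.DataFrame(rows, columns=["event_id", "person_id", "element_concept_id",
                                     "value_as_number", "value_as_concept_id", "src_id"])
    df["domain"] = "observation"
    df["value_as_concept_id"] = pd.to_numeric(df["value_as_concept_id"]).fillna(0).astype("int64")
    return ca.EventStore(df[list(ca.io.EVENT_COLUMNS)])
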