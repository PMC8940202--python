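import numpy as np
import pandas as pd
import pytest

import cohortlink as cl


@pytest.fixture
def tiny_model():
    """Three-term model: Demographics -> {gender, age}."""
    return cl.ReferenceOntology([
        cl.ReferenceTerm("Demographics",
                         cl.ValueDomain("categorical", categories=("recorded",))),
        cl.ReferenceTerm("gender",
                         cl.ValueDomain("categorical",
                                        categories=("female", "male")),
                         parent="Demographics"),
        cl.ReferenceTerm("age",
                         cl.ValueDomain("numeric", unit="years",
                                        numeric_range=(0.0, 120.0)),
                         parent="Demographics"),
    ], name="tiny", version="1.0")


@pytest.fixture(scope="session")
def disease_model():
    return cl.generate_reference()


@pytest.fixture(scope="session")
def disease_corpus(disease_model):
    return cl.build_corpus(disease_model,
                           cl.StaticSynonymSource(cl.CLINICAL_SYNONYMS))


@pytest.fixture(scope="session")
def default_study():
    return cl.generate_study()


@pytest.fixture(scope="session")
def default_spaces(default_study):
    cohorts, truth = default_study
    spaces, aligned, mappings, schema = cl.study_to_spaces(cohorts, truth)
    return spaces, aligned, mappings, schema


def make_table(cohort_id, data):
    """Build a CohortTable from a dict of column -> list of cell strings."""
    return cl.CohortTable(cohort_id, pd.DataFrame(
        {k: [str(v) for v in vals] for k, vals in data.items()}))


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
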