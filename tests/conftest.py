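import numpy as np
import pandas as pd
import pytest

from ineqtrend.data_model import SurveySchema, SurveyTable, exclude_incomplete, ses_rank
from ineqtrend.synthetic import Scenario, generate_microdata

LEVELS = SurveySchema().education_levels


def make_table(rows, schema=None):
    """Build a validated SurveyTable from (country, cluster, year, gender,
    outcome, edu_mother, edu_father) tuples."""
    schema = schema or SurveySchema()
    df = pd.DataFrame(
        rows,
        columns=["country", "cluster", "year", "gender", "outcome",
                 "edu_mother", "edu_father"],
    )
    df.insert(0, "respondent_id", [f"r{i}" for i in range(len(df))])
    df["outcome"] = df["outcome"].astype(float)
    df["year"] = df["year"].astype(int)
    return SurveyTable(data=df, schema=schema)


@pytest.fixture
def toy_table():
    """One country, 4 respondents, two education categories (A < B)."""
    rows = [
        ("AA", "c1", 2003, "boy", 1, LEVELS[0], ""),
        ("AA", "c1", 2003, "girl", 0, LEVELS[0], ""),
        ("AA", "c2", 2003, "boy", 0, LEVELS[2], ""),
        ("AA", "c2", 2003, "girl", 1, LEVELS[2], ""),
    ]
    return make_table(rows)


@pytest.fixture(scope="session")
def small_fit_table():
    """Moderate single-wave clustered sample for GLMM tests."""
    sc = Scenario(
        true_beta0=(-1.0,), true_beta1=(-1.5,), sigma_u=0.5,
        n_countries=4, waves=(2003,), clusters_per_country=12,
        respondents_per_cluster=30, seed=42,
    )
    return generate_microdata(sc)


@pytest.fixture
def ranked(toy_table):
    return ses_rank(exclude_incomplete(toy_table))
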