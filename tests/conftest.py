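import numpy as np
import pandas as pd
import pytest

from reefshift import synthetic


@pytest.fixture(scope="session")
def survey_tables():
    """Small deterministic survey dataset spanning a coral->turf shift."""
    cfg = synthetic.SurveySimConfig(
        sites=("A", "B", "C"),
        transects_per_survey=4,
        survey_dates=("2024-04-15", "2024-07-15", "2025-01-15", "2025-02-10"),
        period_breakpoint="2024-10-01",
        seed=42,
    )
    return synthetic.simulate_surveys(cfg)


@pytest.fixture(scope="session")
def benthic_table(survey_tables):
    return survey_tables[0]


@pytest.fixture(scope="session")
def belt_table(survey_tables):
    return survey_tables[1]


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_community_matrix(rng, n_a=4, n_b=5, n_vars=6):
    """Random wide community matrix with two period labels."""
    n = n_a + n_b
    X = rng.random((n, n_vars))
    df = pd.DataFrame(X, columns=[f"v{j}" for j in range(n_vars)])
    df.insert(0, "period", ["before"] * n_a + ["after"] * n_b)
    df.insert(0, "transect", range(n))
    df.insert(0, "date", pd.Timestamp("2024-06-01"))
    df.insert(0, "site", "S")
    return df
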