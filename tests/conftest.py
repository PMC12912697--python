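import numpy as np
import pandas as pd
import pytest

from hiermort import (
    FeatureSchema,
    FeatureSpec,
    PortfolioTable,
    LearnerSpec,
    assign_folds,
    default_study_config,
    fit_two_step,
    simulate_portfolio,
)

from _scenarios import BASIC_GENERATORS  # noqa: F401  (re-export for tests)


@pytest.fixture
def tiny_schema():
    return FeatureSchema(
        [
            FeatureSpec("age", "metric", "global"),
            FeatureSpec("gender", "categorical", "global"),
            FeatureSpec("occ", "categorical", "local", frozenset({"A", "B"})),
            FeatureSpec("score", "metric", "local", frozenset({"A"})),
        ]
    )


@pytest.fixture
def tiny_table(tiny_schema):
    df = pd.DataFrame(
        {
            "country": ["A", "A", "A", "B", "B", "B"],
            "age": [30.0, 40.0, 50.0, 35.0, 45.0, 55.0],
            "gender": ["M", "F", "M", "F", "M", "F"],
            "occ": ["x", np.nan, "y", "x", "y", np.nan],
            "score": [0.1, -0.5, np.nan, np.nan, np.nan, np.nan],
            "deaths": [1, 0, 2, 0, 1, 3],
            "exposure": [10.0, 20.0, 30.0, 15.0, 25.0, 35.0],
        }
    )
    return PortfolioTable(df, tiny_schema)


@pytest.fixture(scope="session")
def small_study():
    """A reduced default study with folds assigned; shared across tests."""
    config = default_study_config(0.002, seed=11)
    table, truth = simulate_portfolio(config)
    table = assign_folds(table, 0.8, seed=12)
    return config, table, truth


@pytest.fixture(scope="session")
def small_two_step(small_study):
    _, table, _ = small_study
    train, test = table.split()
    model = fit_two_step(train, table.schema, LearnerSpec(seed=13))
    return model, train, test
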