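import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from survpipe.cohort import ColumnSchema, SurvivalDataset

settings.register_profile("suite", max_examples=25, deadline=None)
settings.load_profile("suite")


def make_schema(*covariates: ColumnSchema) -> list[ColumnSchema]:
    return [
        ColumnSchema("duration", "duration", units="months"),
        ColumnSchema("event", "event"),
        *covariates,
    ]


def make_dataset(values: pd.DataFrame, durations, events, covariates) -> SurvivalDataset:
    return SurvivalDataset(
        schema=make_schema(*covariates),
        values=values,
        durations=np.asarray(durations, dtype=float),
        events=np.asarray(events, dtype=float),
    )


@pytest.fixture
def simple_schema():
    return make_schema(
        ColumnSchema("age", "continuous"),
        ColumnSchema("sex", "categorical", levels=("F", "M")),
    )


@pytest.fixture
def simple_dataset(simple_schema):
    values = pd.DataFrame({
        "age": [50.0, 60.0, 70.0, 55.0, 65.0, 45.0],
        "sex": ["F", "M", "F", "M", "F", "M"],
    })
    return SurvivalDataset(
        schema=simple_schema,
        values=values,
        durations=np.array([10.0, 20.0, 5.0, 15.0, 30.0, 25.0]),
        events=np.array([1.0, 0.0, 1.0, 1.0, 0.0, 1.0]),
    )


@pytest.fixture
def correlated_dataset():
    """200 rows where column x duplicates column y up to tiny noise."""
    rng = np.random.default_rng(42)
    n = 200
    y = rng.standard_normal(n)
    x = y + 0.01 * rng.standard_normal(n)
    z = rng.standard_normal(n)
    values = pd.DataFrame({"x": x, "y": y, "z": z})
    return make_dataset(
        values,
        durations=rng.exponential(20.0, n) + 0.1,
        events=np.ones(n),
        covariates=[
            ColumnSchema("x", "continuous"),
            ColumnSchema("y", "continuous"),
            ColumnSchema("z", "continuous"),
        ],
    )
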