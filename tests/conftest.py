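import pandas as pd
import pytest

from adwh import (
    CohortSpec,
    MetricDefinition,
    NumericBinning,
    StaticProfileTable,
    Suppress,
    generate,
)


@pytest.fixture(scope="session")
def small_cohort():
    """200-user, one-week cohort: big enough for buckets, cheap enough for
    brute-force oracles."""
    return generate(CohortSpec(n_users=200, weeks=1, seed=42))


@pytest.fixture(scope="session")
def medium_cohort():
    """2,000-user cohort used where bucket thresholds need headroom."""
    return generate(CohortSpec(n_users=2_000, weeks=1, seed=42))


@pytest.fixture(scope="session")
def default_rules():
    return [Suppress("name"), NumericBinning("age", 10, 0)]


@pytest.fixture(scope="session")
def rhr_definition():
    return MetricDefinition("resting_heart_rate")


@pytest.fixture()
def toy_profiles():
    """Six users with a direct identifier (name) and an age column, built so
    that decade binning yields classes of size >= 2."""
    frame = pd.DataFrame(
        {
            "user_id": ["u1", "u2", "u3", "u4", "u5", "u6"],
            "name": ["Alice", "Bob", "Carol", "Dan", "Eve", "Frank"],
            "age": [23, 27, 34, 38, 35, 21],
        }
    )
    return StaticProfileTable(frame, identifier_columns=("name",))
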