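import numpy as np
import pandas as pd
import pytest

from medroute.synthetic_cohort import (
    Cohort,
    GompertzLifeTableConfig,
    default_scenario,
    generate_cohort,
    generate_life_table,
)


def make_cohort(rows: list[dict], label: str = "test") -> Cohort:
    """Build a small cohort from partial row dicts, filling sane defaults."""
    defaults = {
        "age": 70, "sex": "male", "deprivation": 1, "ethnicity": "white",
        "comorbidity": 0, "route": "elective", "follow_up_months": 60.0,
        "dead": 0, "diagnosis_year": 2010,
    }
    records = []
    for i, row in enumerate(rows):
        rec = {"patient_id": i + 1, **defaults, **row}
        records.append(rec)
    df = pd.DataFrame.from_records(records)
    df["route"] = df["route"].astype(object).where(df["route"].notna(), None)
    return Cohort(df=df, label=label)


@pytest.fixture(scope="session")
def default_spec():
    return default_scenario(n_patients=20_000, seed=42)


@pytest.fixture(scope="session")
def default_cohort(default_spec):
    return generate_cohort(default_spec)


@pytest.fixture(scope="session")
def small_cohort():
    return generate_cohort(default_scenario(n_patients=2_000, seed=7))


@pytest.fixture(scope="session")
def zero_life_table():
    return generate_life_table(GompertzLifeTableConfig(
        b=0.0, age_min=45, age_max=110, year_min=2005, year_max=2021))


@pytest.fixture(scope="session")
def background_life_table():
    return generate_life_table(GompertzLifeTableConfig(
        b=1e-4, c=0.09, age_min=45, age_max=110, year_min=2005, year_max=2021))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
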