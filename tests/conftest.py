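import io

import numpy as np
import pandas as pd
import pytest

import nbcea as nb

SEED = 20260921 % (2**31)


@pytest.fixture(scope="session")
def table1_cost() -> nb.CostConfig:
    return nb.CostConfig(system_incremental_cost=3256.0)


@pytest.fixture(scope="session")
def table1_records(table1_cost):
    return nb.generate_cohort(nb.get_scenario("table1_exact"), seed=1)


@pytest.fixture(scope="session")
def table1_frame(table1_records, table1_cost) -> pd.DataFrame:
    rows = nb.build_analysis_rows(table1_records, table1_cost)
    return nb.analysis_frame(rows)


@pytest.fixture
def four_cell_records():
    """One record in each (arm x delivery) cell, with simple costs."""
    mk = nb.HouseholdRecord
    return [
        mk(id="a", district="intervention", institutional_delivery=1,
           distance_km=2.0, education_head="some", asset_quintile=2,
           household_cost=600.0),
        mk(id="b", district="intervention", institutional_delivery=0,
           distance_km=8.0, education_head="none", asset_quintile=3),
        mk(id="c", district="comparison", institutional_delivery=1,
           distance_km=4.0, education_head="none", asset_quintile=1,
           household_cost=500.0),
        mk(id="d", district="comparison", institutional_delivery=0,
           distance_km=6.0, education_head="some", asset_quintile=5),
    ]


def random_analysis_frame(rng: np.random.Generator, n: int | None = None) -> pd.DataFrame:
    """Small random two-arm analysis frame for oracle/property tests."""
    if n is None:
        n = int(rng.integers(6, 51))
    sci = np.zeros(n, dtype=int)
    sci[: n // 2] = 1
    effect = rng.integers(0, 2, size=n)
    df = pd.DataFrame(
        {
            "id": [f"r{i}" for i in range(n)],
            "sci": sci,
            "effect": effect,
            "societal_cost": np.round(rng.gamma(2.0, 1500.0, size=n), 2),
            "edu_some": rng.integers(0, 2, size=n),
            "dist_far": rng.integers(0, 2, size=n),
            "asset_quintile": rng.integers(1, 6, size=n),
        }
    )
    for q in (2, 3, 4, 5):
        df[f"asset_q{q}"] = (df["asset_quintile"] == q).astype(int)
    return df


def csv_stream(text: str) -> io.StringIO:
    return io.StringIO(text.strip() + "\n")
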