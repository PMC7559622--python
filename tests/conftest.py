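import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from pocdkit import BatteryDef, GenotypeTable
from pocdkit.battery import TIMEPOINTS

settings.register_profile("default", derandomize=True, max_examples=100)
settings.load_profile("default")


@pytest.fixture
def day7_table() -> GenotypeTable:
    """Published day-7 genotype counts by POCD status."""
    return GenotypeTable(cases=(10, 16, 3), noncases=(11, 39, 20), label="7 days")


@pytest.fixture
def month3_table() -> GenotypeTable:
    """Published month-3 genotype counts by POCD status."""
    return GenotypeTable(cases=(8, 12, 5), noncases=(13, 43, 18), label="3 months")


@pytest.fixture
def battery() -> BatteryDef:
    return BatteryDef.default()


def make_random_cohort(
    rng: np.random.Generator,
    n_patients: int,
    n_controls: int,
    battery: BatteryDef,
    missing_frac: float = 0.0,
) -> pd.DataFrame:
    """Raw random cohort frame built independently of the simulator, for
    oracle tests: arbitrary scores, optional missing patient cells."""
    n = n_patients + n_controls
    data = {
        "id": [f"R{i}" for i in range(n)],
        "arm": ["patient"] * n_patients + ["control"] * n_controls,
        "genotype": rng.integers(0, 3, n),
        "age": rng.normal(70, 5, n).round(1),
        "sex": rng.choice(["male", "female"], n),
        "education_years": rng.integers(0, 12, n).astype(float),
    }
    for tp in TIMEPOINTS:
        for t in battery.tests:
            col = rng.normal(rng.uniform(10, 400), rng.uniform(2, 30), n)
            if missing_frac and tp != "baseline":
                mask = rng.random(n) < missing_frac
                mask[n_patients:] = False  # controls stay complete
                col = np.where(mask, np.nan, col)
            data[battery.score_column(t, tp)] = col
    return pd.DataFrame(data)


@pytest.fixture
def random_cohort_factory(battery):
    def factory(seed: int, n_patients: int = 12, n_controls: int = 6,
                missing_frac: float = 0.0) -> pd.DataFrame:
        return make_random_cohort(
            np.random.default_rng(seed), n_patients, n_controls, battery,
            missing_frac=missing_frac,
        )

    return factory
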