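import numpy as np
import pandas as pd
import pytest

from gfrcompare import CohortSpec, generate_cohort


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240428)


@pytest.fixture(scope="session")
def default_cohort_frame():
    """A default-spec synthetic cohort reused across read-only tests."""
    return generate_cohort(CohortSpec(seed=101)).to_frame()


@pytest.fixture()
def noiseless_lmr_frame():
    """Small cohort whose LMR estimate reproduces mGFR exactly."""
    spec = CohortSpec(n=150, error_sd=0.0, truth_equation="lmr", seed=55)
    return generate_cohort(spec).to_frame()


@pytest.fixture()
def dirty_cohort_csv(tmp_path):
    """Cohort file with a known set of invalid rows (hand-counted)."""
    df = pd.DataFrame(
        {
            "id": [f"P{i}" for i in range(8)],
            "age": [45, 17, 60, 50, 55, 40, 70, 33],
            "sex": ["m", "f", "x", "female", "m", "f", "male", "f"],
            "pcr_mg_dl": [1.2, 1.0, 1.1, 0.0, 1.4, 0.9, 1.8, 1.1],
            "mgfr": [50.0, 60.0, 55.0, 48.0, np.nan, 62.0, 35.0, 70.0],
        }
    )
    path = tmp_path / "cohort.csv"
    df.to_csv(path, index=False)
    # valid rows: P0, P5, P7 plus P4 when mgfr not required
    return path
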