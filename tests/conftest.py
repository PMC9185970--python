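import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from epifluct.simulate import (
    generate_cell_references,
    generate_clock,
    generate_longitudinal_betas,
    generate_study_design,
)

settings.register_profile("suite", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def small_design():
    return generate_study_design(2, 2, 8, day_spacing=[1, 3, 1, 5, 2, 1, 4], seed=11)


@pytest.fixture(scope="session")
def references():
    return generate_cell_references(3, 400, 0.5, seed=7)


@pytest.fixture(scope="session")
def gen_clock():
    return generate_clock(
        60, 0.0, ("normal", 0, 0.15), transform=("horvath", 20.0),
        coupling=0.8, seed=5, center_age=40.0,
    )


@pytest.fixture(scope="session")
def simulated(small_design, references, gen_clock):
    matrix, truth = generate_longitudinal_betas(
        small_design, gen_clock, references, seed=13
    )
    return matrix, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)


def make_age_table(days, ages, individual="person_A", sample_type="PBMC",
                   clock_name="clock", normalization="raw", corrected=False):
    """Build a minimal age table for one series."""
    return pd.DataFrame(
        {
            "sample_id": [f"{individual}_{sample_type}_d{d:03d}" for d in days],
            "individual": individual,
            "sample_type": sample_type,
            "day": list(days),
            "clock_name": clock_name,
            "normalization": normalization,
            "corrected": corrected,
            "epigenetic_age": list(ages),
        }
    )
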