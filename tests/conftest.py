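import numpy as np
import pandas as pd
import pytest

from cogload.config import make_config
from cogload.scoring import score_cohort
from cogload.synthetic import generate_cohort


@pytest.fixture(scope="session")
def default_cohort() -> pd.DataFrame:
    """One default-condition cohort (n = 81), raw measures only."""
    return generate_cohort(make_config(n_participants=81, seed=7))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort) -> pd.DataFrame:
    scored, _ = score_cohort(default_cohort)
    return scored


@pytest.fixture(scope="session")
def large_cohort() -> pd.DataFrame:
    """A calibration-sized cohort (n = 2000) under default conditions."""
    return generate_cohort(make_config(n_participants=2000, seed=11))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
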