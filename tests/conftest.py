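from pathlib import Path

import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "ci", derandomize=True, deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")

DATA = Path(__file__).parent / "data"


@pytest.fixture(scope="session")
def mini_csv() -> Path:
    return DATA / "mini_survey.csv"


@pytest.fixture(scope="session")
def mini_df(mini_csv) -> pd.DataFrame:
    return pd.read_csv(mini_csv)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
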