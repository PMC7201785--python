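import logging

import numpy as np
import pandas as pd
import pytest

from tonguethermo import RainbowPalette, sample_cohort

logging.disable(logging.WARNING)


@pytest.fixture(scope="session")
def palette() -> RainbowPalette:
    return RainbowPalette()


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    return sample_cohort(12, 12, seed=3)


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def normal_record() -> pd.Series:
    return pd.Series({"tst": 34.62, "group": "normal", "subject_id": "N000"})


@pytest.fixture(scope="session")
def diabetic_record() -> pd.Series:
    return pd.Series({"tst": 35.23, "group": "diabetic", "subject_id": "D000"})
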