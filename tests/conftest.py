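import datetime as dt

import numpy as np
import pytest

from sleepvar import cohort


@pytest.fixture(scope="session")
def default_arch():
    return cohort.SleepArchitecture(
        mean_bedtime=-81, bedtime_sd=40, mean_duration=481, duration_sd=45,
        awakening_rate=17.5, awakening_length_mean=2.5)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact synthetic cohort shared by aggregation/association tests."""
    return cohort.generate_cohort(n_asd=30, n_td=10, seed=11)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def a_date():
    return dt.date(2020, 3, 2)
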