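import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from actimood.cohort import EpochSeries
from actimood.config import ActigraphyParams, CohortConfig

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_series(values, epoch_s=60, wear=None, start="2014-06-02 12:00:00"):
    values = np.asarray(values, dtype=float)
    if wear is None:
        wear = np.ones(values.size, dtype=bool)
    return EpochSeries(start=pd.Timestamp(start), epoch_s=epoch_s, values=values, wear=wear)


@pytest.fixture
def deterministic_params():
    """Actigraphy parameters with every stochastic component switched off."""
    return ActigraphyParams(
        noise_sd=0.0,
        sleep_noise_sd=0.0,
        sleep_onset_sd_h=0.0,
        sleep_length_sd_h=0.0,
        phase_jitter_sd_h=0.0,
        fragmentation_rate_per_h=0.0,
        wake_bout_prob=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    from actimood.cohort import generate_cohort

    return generate_cohort(CohortConfig(n_participants=600, seed=123))
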