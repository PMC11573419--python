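import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from sepsisrl import CohortConfig, generate_cohort
from sepsisrl.preprocessing import preprocess

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_cohort():
    """300-patient default cohort shared across tests."""
    return generate_cohort(CohortConfig(n_patients=300, seed=8))


@pytest.fixture(scope="session")
def small_table(small_cohort):
    return preprocess(small_cohort)


def make_events(rows):
    """events table from (patient_id, time, type) triples."""
    return pd.DataFrame(rows, columns=["patient_id", "event_time", "event_type"])
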