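import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from icovnet.io import CohortTable
from icovnet.synthetic import SimConfig, generate_cohort
from icovnet.variables import default_registry

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("default")


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def cohort(registry):
    """Default synthetic cohort, seed 1 (the standard study-size conditions)."""
    return generate_cohort(SimConfig(seed=1), registry)


@pytest.fixture()
def small_cohort(registry):
    """Six participants, enough for correlation plumbing but fast."""
    return generate_cohort(SimConfig(n_participants=6, seed=7), registry)


def make_cohort_frame(values, registry):
    """Helper: wrap a raw participants x 18 array into a CohortTable."""
    names = [s.name for s in registry]
    ids = [f"p{i}" for i in range(len(values))]
    frame = pd.DataFrame(np.asarray(values, dtype=float), index=ids, columns=names)
    return CohortTable(frame, registry)
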