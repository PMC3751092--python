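import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import waistmi as wm

settings.register_profile(
    "ci",
    derandomize=True,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def complete_table():
    """One complete event-rich dataset (n=4,000) shared across tests."""
    cfg = wm.desk_profile(master_seed=123, n=4_000)
    return wm.simulate_complete(cfg, np.random.SeedSequence(99))


@pytest.fixture(scope="session")
def big_cohort():
    """Large covariate+exposure table for distributional checks."""
    table = wm.generate_covariates(wm.CohortConfig(), n=100_000, seed=7)
    return wm.simulate_waist(table, seed=8)
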