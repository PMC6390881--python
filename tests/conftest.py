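import numpy as np
import pandas as pd
import pytest

from metacog.observers import CohortConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


@pytest.fixture(scope="session")
def small_cohort() -> pd.DataFrame:
    """A small but fully structured two-group cohort (6 per group)."""
    return simulate_cohort(CohortConfig(n_per_group=6), seed=77)


@pytest.fixture(scope="session")
def small_cohort_null() -> pd.DataFrame:
    """Same design with all training drifts disabled in both groups."""
    cfg = CohortConfig(
        n_per_group=6,
        conf_bias_drift_mean=0.0,
        conf_bias_drift_sd=0.0,
        efficiency_per_bias=0.0,
        efficiency_drift_sd=0.0,
    )
    return simulate_cohort(cfg, seed=78)
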