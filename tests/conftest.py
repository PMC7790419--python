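import numpy as np
import pytest

from pefrisk.cohort import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """Six synthetic patients with 60-120-day series; shared across tests."""
    config = CohortConfig(n_patients=6, min_days=60, max_days=120, seed=42)
    return generate_cohort(config)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
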