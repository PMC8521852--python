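import numpy as np
import pytest

from wearday.preprocess import preprocess_logs
from wearday.simulate import CohortConfig, generate_cohort


@pytest.fixture(scope="session")
def small_cohort():
    """120-user default-condition cohort shared across module tests."""
    cfg = CohortConfig(n_users=120, seed=7)
    logs, truth = generate_cohort(cfg)
    return cfg, logs, truth


@pytest.fixture(scope="session")
def small_matrix(small_cohort):
    _, logs, truth = small_cohort
    A, audit = preprocess_logs(logs, truth.windows)
    return A, audit


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
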