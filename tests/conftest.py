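import numpy as np
import pytest

from erpdx.erp_data import default_registry
from erpdx.features import smoke_window_params
from erpdx.synthetic import CohortConfig, default_components, simulate_cohort


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def components(registry):
    return default_components(registry)


@pytest.fixture(scope="session")
def small_cohort():
    """16-subject default-effect cohort, enough for 3-4 fold CV."""
    return simulate_cohort(CohortConfig(n_healthy=10, n_patient=6, seed=7))


@pytest.fixture(scope="session")
def medium_cohort():
    """60-subject default-effect cohort for pipeline-level tests."""
    return simulate_cohort(CohortConfig(n_healthy=40, n_patient=20, seed=3))


@pytest.fixture(scope="session")
def smoke_params(registry):
    return smoke_window_params(registry)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
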