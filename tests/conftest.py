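import numpy as np
import pytest

from trialglm.design import assemble_design_matrix
from trialglm.session import SessionConfig, simulate_trial_events


@pytest.fixture(scope="session")
def small_bundle():
    """A 30-trial expert session shared by read-only tests."""
    return simulate_trial_events(SessionConfig(n_trials=30, seed=123))


@pytest.fixture(scope="session")
def small_design(small_bundle):
    return assemble_design_matrix(small_bundle)


@pytest.fixture(scope="session")
def cv_bundle():
    """A 40-trial session large enough for 10-fold cross-validation."""
    return simulate_trial_events(SessionConfig(n_trials=40, seed=321))


@pytest.fixture(scope="session")
def cv_design(cv_bundle):
    return assemble_design_matrix(cv_bundle)


@pytest.fixture
def rng():
    return np.random.default_rng(7)
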