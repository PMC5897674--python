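import warnings

import numpy as np
import pytest

from spiba.synthetic_data import DEFAULT_TARGET, simulate_pointing_session


@pytest.fixture(autouse=True)
def _quiet_expected_warnings():
    # small-sample CI warnings and missed-offset notices are part of the
    # exercised behaviour; keep test output readable
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        yield


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_session():
    """A 20-trial simulated block with its planted ground truth."""
    return simulate_pointing_session(
        n_trials=20, condition="low_load", gamma_params=(2.5, 0.08), seed=3
    )


@pytest.fixture(scope="session")
def full_session():
    """The study-sized 60-trial block used for end-to-end recovery."""
    return simulate_pointing_session(
        n_trials=60, condition="low_load", gamma_params=(2.5, 0.08), seed=1
    )


@pytest.fixture
def target():
    return DEFAULT_TARGET
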