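import warnings

import numpy as np
import pytest

from lumbarload import SubjectInfo, scale_body_model
from lumbarload.pipeline import prepare_session
from lumbarload.simulate import simulate_session

warnings.filterwarnings("ignore", message="only .* samples")


@pytest.fixture(scope="session")
def subject():
    """The cohort's mean subject: 1.85 m, 93 kg."""
    return SubjectInfo(id="s1", height=1.85, mass=93.0)


@pytest.fixture(scope="session")
def body(subject):
    return scale_body_model(subject)


@pytest.fixture(scope="session")
def default_session():
    """One full simulated session at default noise (do not mutate)."""
    return simulate_session(seed=1, tap_offset=0.25)


@pytest.fixture(scope="session")
def prepared_session():
    """A session after synchronization + calibration (segment frames)."""
    return prepare_session(simulate_session(seed=3, tap_offset=-0.2))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
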