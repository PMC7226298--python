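import numpy as np
import pytest

from hdlflux import synthetic


@pytest.fixture
def design():
    """Default study protocol (12-point schedule, 5 loading doses)."""
    return synthetic.StudyDesign()


@pytest.fixture
def rng():
    return np.random.default_rng(20260926)


@pytest.fixture(scope="session")
def truth():
    return synthetic.GroundTruth.default()
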