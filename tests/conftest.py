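import numpy as np
import pytest

from motionmask.filters import insect_bank, mammal_bank
from motionmask.simulation import insect_model, mammal_model


@pytest.fixture(scope="session")
def ibank():
    return insect_bank()


@pytest.fixture(scope="session")
def mbank():
    return mammal_bank()


@pytest.fixture(scope="session")
def iarray():
    """Calibrated insect detector array (10 detectors over 40 degrees)."""
    return insect_model()


@pytest.fixture(scope="session")
def marray():
    """Calibrated mammal detector array."""
    return mammal_model()


@pytest.fixture()
def rng():
    return np.random.default_rng(20260925)
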