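import numpy as np
import pytest

from motorchain import default_parameters
from motorchain.model import MotorEnsembleModel


@pytest.fixture(scope="session")
def p_default():
    return default_parameters()


@pytest.fixture(scope="session")
def m2_model():
    """Two-motor ensemble at defaults (zero load, thermal noise on)."""
    return MotorEnsembleModel(default_parameters(m_bar=2))


@pytest.fixture(scope="session")
def m3_model():
    """Three-motor ensemble at defaults."""
    return MotorEnsembleModel(default_parameters(m_bar=3))


@pytest.fixture(scope="session")
def m2_qsd(m2_model):
    return m2_model.quasi_stationary()


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)
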