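import numpy as np
import pytest

from dnmrfit import COMPOUND25_D2O, DEFAULT_MIXING_TIMES


@pytest.fixture(scope="session")
def preset():
    """Reference D2O parameter set used throughout the suite."""
    return COMPOUND25_D2O


@pytest.fixture(scope="session")
def mixing_times():
    return DEFAULT_MIXING_TIMES


@pytest.fixture(scope="session")
def ppm_axis():
    """Dense axis over the methoxy window."""
    return np.linspace(3.75, 3.95, 2048)
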