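import numpy as np
import pytest

from cistrack.config import AnalysisConfig
from cistrack.simulate import SimParams, simulate_study


@pytest.fixture()
def cfg():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def tiny_study():
    """Tiny synthetic study shared across unit tests (read-only)."""
    return simulate_study(SimParams.tiny(seed=7))


@pytest.fixture(scope="session")
def default_study():
    """Default-size synthetic study shared across slower tests (read-only)."""
    return simulate_study(SimParams(seed=11))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
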