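import numpy as np
import pytest

from excitonmash.model import (
    ContinuousComponent,
    DiscreteMode,
    DiscretizedBath,
    SpectralDensity,
)
from excitonmash.synthetic import make_dimer


@pytest.fixture
def debye():
    return ContinuousComponent("debye", lam=100.0, omega_c=53.0)


@pytest.fixture
def dimer_sd():
    return SpectralDensity(
        discrete=(DiscreteMode(180.0, 0.5),),
        continuous=(ContinuousComponent("debye", lam=100.0, omega_c=53.0),),
    )


@pytest.fixture
def asym_dimer():
    """Asymmetric dimer with one strongly coupled high-frequency mode."""
    system, _ = make_dimer(200.0, 100.0)
    high = DiscretizedBath(frequencies=np.array([1200.0]),
                           couplings=np.array([np.sqrt(0.3)]))
    return system, high


@pytest.fixture
def rng():
    return np.random.default_rng(42)
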