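import numpy as np
import pytest

from tfdeconv.simulate import SimConfig, simulate
from tfdeconv.spectral import SpectralConfig, mtm_spectrogram

# a priori seed for every stochastic check in the suite
SEED = 1234


@pytest.fixture(scope="session")
def short_sim():
    """60 s default-parameter source-mixing simulation (12 ERS events)."""
    return simulate(SimConfig(duration_s=60.0, latency_sd_s=0.25, seed=SEED))


@pytest.fixture(scope="session")
def beta_spectral():
    """Reduced frequency axis covering the simulated beta band."""
    return SpectralConfig(freqs=np.arange(10.0, 40.1, 2.5))


@pytest.fixture(scope="session")
def short_power(short_sim, beta_spectral):
    return mtm_spectrogram(short_sim.signal, beta_spectral)
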