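import numpy as np
import pytest

from phasorflim import AcquisitionConfig, SpectralChannelMap, make_phantom


@pytest.fixture(scope="session")
def channel_map():
    return SpectralChannelMap.default()


@pytest.fixture(scope="session")
def acq():
    return AcquisitionConfig()


@pytest.fixture(scope="session")
def acq_fast():
    """Coarse timing grid, no IRF: cheap decays for fit tests."""
    return AcquisitionConfig(n_time_bins=64, irf_fwhm=0.0)


@pytest.fixture(scope="session")
def bcc_phantom():
    return make_phantom("bcc", seed=11, shape=(64, 64))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
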