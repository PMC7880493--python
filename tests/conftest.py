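import numpy as np
import pytest

from itdppc import StimulusParams, make_prior
from itdppc.ideal_observer import DelayGrid

#: BC levels implied by the standard external-noise amplitudes
BC_LEVELS = (0.9375, 0.4071, 0.19, 0.0975)

DT_US = 1e6 / 48000


@pytest.fixture(scope="session")
def box_grid():
    """The standard 25-point delay grid with a flat prior."""
    return make_prior("box")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def toy_grid():
    """Small 9-point grid usable with very short (T >= 16) stimuli."""
    deltas = np.arange(-4, 5) * DT_US
    return DelayGrid(deltas, np.full(9, -np.log(9.0)))


def toy_params(t=16, seed=0, sigma_s=0.8, sigma_n=0.6, sigma_0=0.5,
               delta_samples=2, lowpass=None):
    """Unfiltered short stimulus parameters for exact covariance oracles."""
    return StimulusParams(
        sigma_s=sigma_s, sigma_n=sigma_n, sigma_0=sigma_0,
        delta_us=delta_samples * DT_US, duration=t / 48000,
        lowpass_cutoff=lowpass, seed=seed,
    )
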