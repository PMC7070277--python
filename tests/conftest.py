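import numpy as np
import pytest

from gaitgrnn import GaitParameters, generate_recording


@pytest.fixture(scope="session")
def small_recording():
    """A 12-cycle default-noise recording shared by pipeline tests."""
    return generate_recording(GaitParameters(n_cycles=12, seed=3))


@pytest.fixture(scope="session")
def quiet_recording():
    """A noiseless, spike-free recording for exact-alignment checks."""
    params = GaitParameters(
        n_cycles=8,
        seed=5,
        angle_noise_sd=0.0,
        pressure_spike_prob=0.0,
        semg_amp_cv=0.0,
    )
    return generate_recording(params)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
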