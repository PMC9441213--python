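import numpy as np
import pytest

import specklesense as ss


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def fiber():
    return ss.FiberSpec()


@pytest.fixture(scope="session")
def tiny_acquisition():
    """A very small, fast acquisition for unit tests."""
    return ss.AcquisitionConfig(frame_rate_hz=500.0, duration_s=0.2,
                                frame_shape=(32, 32), drive_freq_hz=140.0)


@pytest.fixture(scope="session")
def tiny_recording(fiber, tiny_acquisition):
    return ss.simulate_recording(fiber, tiny_acquisition,
                                 ss.GlucoseSample(105.0), seed=7, n_modes=24)
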