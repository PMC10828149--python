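import numpy as np
import pytest

from fractalconn.preprocess import EEGRecording


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def white_recording(rng):
    """Four channels of white noise at 256 Hz, 8 s."""
    return EEGRecording(rng.standard_normal((4, 2048)), 256.0,
                        ["F3", "F4", "P3", "P4"])
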