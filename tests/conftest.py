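import numpy as np
import pytest

from radarvitals import RadarConfig


@pytest.fixture(scope="session")
def radar_config():
    return RadarConfig()


@pytest.fixture(scope="session")
def prf(radar_config):
    return radar_config.prf


def breathing_trace(freq_hz, amplitude_mm, duration_s, fs, harmonics=()):
    """Plain multi-harmonic breathing displacement for filter tests."""
    t = np.arange(0, duration_s, 1.0 / fs)
    x = amplitude_mm * np.sin(2 * np.pi * freq_hz * t)
    for k, w in enumerate(harmonics, start=2):
        x += amplitude_mm * w * np.sin(2 * np.pi * k * freq_hz * t)
    return t, x
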