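import numpy as np
import pytest

from pigsound.preprocess import Waveform


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def noisy_sine(rng):
    """1 s, 8 kHz sinusoid burst in white noise at 0 dB, with the clean part."""
    n = 8000
    t = np.arange(n) / 8000.0
    clean = np.zeros(n)
    clean[3000:6000] = 0.3 * np.sin(2 * np.pi * 625 * t[3000:6000])
    noise = rng.standard_normal(n)
    noise *= np.sqrt(np.sum(clean**2) / np.sum(noise**2))
    return Waveform(clean + noise), clean, noise
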