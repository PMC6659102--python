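import numpy as np
import pytest

from hippoephys import TimeSeries


@pytest.fixture
def rate() -> float:
    return 1000.0


@pytest.fixture
def two_tone(rate):
    """8 Hz + 40 Hz unit tones with SNR-10 white noise, 10 s."""
    t = np.arange(0, 10.0, 1 / rate)
    rng = np.random.default_rng(42)
    noise_sd = np.sqrt(0.5 / 10)  # tone power 0.5 each, SNR 10 per tone
    x = (
        np.sin(2 * np.pi * 8 * t)
        + np.sin(2 * np.pi * 40 * t)
        + noise_sd * rng.standard_normal(t.size)
    )
    return TimeSeries(x, rate, units="mV", channel_id="two-tone")


def make_tone(freq, rate=1000.0, duration=2.0, amplitude=1.0, phase=0.0):
    t = np.arange(0, duration, 1 / rate)
    return TimeSeries(amplitude * np.sin(2 * np.pi * freq * t + phase), rate)
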