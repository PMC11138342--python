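import numpy as np
import pytest
from hypothesis import settings

from difc import CHANNELS, ChannelId, Scan

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_scan(n=2000, fs=1000.0, fill=0.0, rng=None, noise=0.0, **kwargs):
    """Small four-channel scan; optional Gaussian noise."""
    sig = {}
    for ch in CHANNELS:
        v = np.full(n, fill, dtype=float)
        if rng is not None and noise:
            v = v + noise * rng.standard_normal(n)
        sig[ch] = v
    return Scan(sampling_rate=fs, signal=sig, **kwargs)


def gaussian_pulse(n, fs, center_s, amp, fwhm_s):
    t = np.arange(n) / fs
    sig = fwhm_s / (2 * np.sqrt(2 * np.log(2)))
    return amp * np.exp(-0.5 * ((t - center_s) / sig) ** 2)


@pytest.fixture
def scan_factory():
    return make_scan


@pytest.fixture
def pulse_factory():
    return gaussian_pulse
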