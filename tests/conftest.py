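import numpy as np
import pytest

from qeegprog import EegRecording, epoch_windows, welch_psd

FS = 250.0


def sine_recording(components, fs=FS, duration_s=600.0, labels=("C3", "C4")):
    """Recording whose channels are all the same sum of (freq, amp) sines."""
    t = np.arange(int(duration_s * fs)) / fs
    x = sum(a * np.sin(2 * np.pi * f * t) for f, a in components)
    data = np.tile(x, (len(labels), 1))
    return EegRecording(list(labels), fs, data)


@pytest.fixture(scope="session")
def sine10():
    """Pure unit-amplitude 10 Hz sine, two channels, 10 min."""
    return sine_recording([(10.0, 1.0)])


@pytest.fixture(scope="session")
def sine10_spectrum(sine10):
    ep = epoch_windows(sine10)
    return ep, welch_psd(ep)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240915)
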