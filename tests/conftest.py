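import numpy as np
import pytest

from swdus import SignalRecord, default_calibration

FS = 1000.0


def pearson(a, b):
    a = np.asarray(a, float) - np.mean(a)
    b = np.asarray(b, float) - np.mean(b)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return 0.0
    return float(np.dot(a, b) / (na * nb))


def tone(freq_hz, duration_s=4.0, fs=FS, amp=1.0):
    t = np.arange(int(duration_s * fs)) / fs
    return amp * np.sin(2 * np.pi * freq_hz * t)


@pytest.fixture(scope="session")
def calibration():
    """Calibrated default preset family at 1 kHz (shared across the run)."""
    return default_calibration(FS)


@pytest.fixture()
def record():
    def make(samples, fs=FS):
        return SignalRecord(np.asarray(samples, float), fs)

    return make
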