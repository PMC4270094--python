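import numpy as np
import pytest

from ripplelock.core import LFPRecording
from ripplelock.sessions import ripple_session


def tone(freq: float, duration: float = 1.0, fs: float = 1000.0, amplitude: float = 1.0,
         trough_start: bool = True) -> LFPRecording:
    """Pure tone; by default -cos so the trace starts at a trough."""
    t = np.arange(0.0, duration, 1.0 / fs)
    wave = -np.cos(2 * np.pi * freq * t) if trough_start else np.sin(2 * np.pi * freq * t)
    return LFPRecording(amplitude * wave, fs)


@pytest.fixture(scope="session")
def small_ripple_session():
    """One 300 s rest session with 20 planted high-SNR events, shared by
    detection-oriented tests."""
    return ripple_session(seed=11, rest_duration=300.0, n_events=20, snr=8.0)
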