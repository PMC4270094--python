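"""Band-pass decomposition, downsampling, envelopes and time-frequency maps.

All filtering is zero-phase (forward-backward Butterworth) so that trough and
peak times — the anchors of the 0-deg-trough phase convention — are not
displaced by filter group delay.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import LFPRecording

__all__ = [
    "OscillationBand",
    "BANDS",
    "FilterbankGrid",
    "TimeFrequencyMap",
    "bandpass",
    "downsample",
    "envelope",
    "filterbank_power",
    "triggered_average",
]


@dataclass(frozen=True)
class OscillationBand:
    """A named frequency band (Hz)."""

    name: str
    low: float
    high: float

    def __post_init__(self) -> None:
        if not 0 < self.low < self.high:
            raise ValueError("band edges must satisfy 0 < low < high")


#: Canonical hippocampal bands: theta/gamma/epsilon during running, ripple
#: during rest. Epsilon and ripple overlap by construction (90-130 within
#: 90-200); they are distinguished by behavioral state, not spectrum alone.
BANDS: dict[str, OscillationBand] = {
    "theta": OscillationBand("theta", 5.0, 10.0),
    "gamma": OscillationBand("gamma", 25.0, 90.0),
    "epsilon": OscillationBand("epsilon", 90.0, 130.0),
    "ripple": OscillationBand("ripple", 90.0, 200.0),
}


def bandpass(trace: LFPRecording, band: OscillationBand, order: int = 4) -> LFPRecording:
    """Zero-phase Butterworth band-pass.

    Applied forward-backward (``sosfiltfilt``), so the effective magnitude
    response is squared but the phase response is identically zero: passband
    tones keep their amplitude within a few percent and transient peaks are
    not shifted in time.
    """
    nyq = trace.fs / 2.0
    if band.high >= nyq:
        raise ValueError(
            f"band {band.name} ({band.low}-{band.high} Hz) exceeds Nyquist ({nyq} Hz)"
        )
    sos = sps.butter(order, [band.low, band.high], btype="bandpass", fs=trace.fs, output="sos")
    return LFPRecording(sps.sosfiltfilt(sos, trace.data), trace.fs)


def _decimation_stages(factor: int) -> list[int]:
    """Split a decimation factor into stages <= 10 for filter stability."""
    stages: list[int] = []
    remaining = factor
    while remaining > 10:
        for q in (10, 9, 8, 7, 6, 5, 4, 3, 2):
            if remaining % q == 0:
                stages.append(q)
                remaining //= q
                break
        else:  # prime factor > 10: decimate by it directly
            stages.append(remaining)
            remaining = 1
    if remaining > 1:
        stages.append(remaining)
    return stages


def downsample(trace: LFPRecording, factor: int) -> LFPRecording:
    """Anti-aliased decimation by an integer factor (zero-phase FIR)."""
    if factor != int(factor) or factor < 1:
        raise ValueError("downsampling factor must be a positive integer")
    factor = int(factor)
    if factor == 1:
        return trace.copy()
    data = trace.data
    fs = trace.fs
    for q in _decimation_stages(factor):
        data = sps.decimate(data, q, ftype="fir", zero_phase=True)
        fs /= q
    return LFPRecording(data, fs)


def envelope(trace: LFPRecording) -> LFPRecording:
    """Instantaneous amplitude as the magnitude of the analytic signal.

    The input is expected to be band-passed; for a pure tone of amplitude A
    the result is A everywhere away from the trace edges.
    """
    from scipy.fft import next_fast_len

    n = trace.data.size
    nfft = next_fast_len(n)  # pad to a fast FFT length, then trim
    env = np.abs(sps.hilbert(trace.data, N=nfft)[:n])
    return LFPRecording(env, trace.fs)


@dataclass(frozen=True)
class FilterbankGrid:
    """Narrow-band filterbank layout: centers start..stop step apart, each
    band ``bandwidth`` Hz wide. The default (10-200 Hz, 2 Hz steps, 4 Hz
    bands) yields 96 center frequencies."""

    start: float = 10.0
    stop: float = 200.0
    step: float = 2.0
    bandwidth: float = 4.0

    @property
    def centers(self) -> np.ndarray:
        n = int(round((self.stop - self.start) / self.step)) + 1
        return self.start + self.step * np.arange(n)


@dataclass
class TimeFrequencyMap:
    """Z-scored narrow-band power, rows indexed by center frequency."""

    values: np.ndarray  # (n_freqs, n_times)
    freqs: np.ndarray  # Hz
    times: np.ndarray  # s (absolute, or relative to trigger after averaging)
    trigger: str = "none"
    n_triggers: int = 0

    def row(self, freq: float) -> np.ndarray:
        idx = int(np.argmin(np.abs(self.freqs - freq)))
        return self.values[idx]


def filterbank_power(
    trace: LFPRecording,
    grid: FilterbankGrid = FilterbankGrid(),
    power: str = "squared",
    order: int = 2,
) -> TimeFrequencyMap:
    """Narrow-band envelope power map, z-scored per frequency band.

    ``power`` selects whether the squared envelope (default, matching
    "z-scored power" colorbars) or the envelope itself is normalized.
    """
    if grid.stop >= trace.fs / 2:
        raise ValueError("filterbank grid exceeds Nyquist frequency")
    if power not in ("squared", "envelope"):
        raise ValueError("power must be 'squared' or 'envelope'")
    centers = grid.centers
    half = grid.bandwidth / 2.0
    rows = np.empty((centers.size, trace.data.size))
    for i, fc in enumerate(centers):
        band = OscillationBand(f"{fc:g}Hz", fc - half, fc + half)
        env = envelope(bandpass(trace, band, order=order)).data
        p = env**2 if power == "squared" else env
        sd = p.std()
        rows[i] = (p - p.mean()) / sd if sd > 0 else p - p.mean()
    return TimeFrequencyMap(rows, centers, trace.times)


def triggered_average(
    tfmap: TimeFrequencyMap,
    triggers,
    window: tuple[float, float],
) -> TimeFrequencyMap:
    """Average the map across windows aligned to trigger times.

    ``window = (pre, post)`` in seconds; triggers whose window would extend
    past either edge of the map are dropped (their count is reflected in
    ``n_triggers``). Raises if no trigger has a full window.
    """
    pre, post = window
    if pre < 0 or post < 0:
        raise ValueError("window extents must be non-negative")
    dt = float(np.median(np.diff(tfmap.times)))
    t0 = tfmap.times[0]
    n_pre = int(round(pre / dt))
    n_post = int(round(post / dt))
    n_times = tfmap.values.shape[1]
    used = 0
    acc = np.zeros((tfmap.values.shape[0], n_pre + n_post + 1))
    for trig in np.atleast_1d(np.asarray(triggers, dtype=float)):
        idx = int(round((trig - t0) / dt))
        if idx - n_pre < 0 or idx + n_post >= n_times:
            continue
        acc += tfmap.values[:, idx - n_pre : idx + n_post + 1]
        used += 1
    if used == 0:
        raise ValueError("no trigger has a full window inside the map")
    rel_times = dt * np.arange(-n_pre, n_post + 1)
    return TimeFrequencyMap(acc / used, tfmap.freqs.copy(), rel_times, "triggered", used)
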