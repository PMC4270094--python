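"""Core containers shared across the pipeline.

Conventions used throughout the package:

* time is in seconds, frequency in Hz, voltage in mV;
* oscillation phase is in degrees with 0 deg = cycle trough, 180 deg = peak
  (ascending limb 0->180, descending 180->360);
* intervals are half-open ``[start, end)`` pairs in seconds, kept sorted and
  disjoint.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "LFPRecording",
    "SpeedTrace",
    "SpikeTrain",
    "OscillationEvent",
    "intervals_duration",
    "in_intervals",
    "validate_intervals",
]


@dataclass
class LFPRecording:
    """A uniformly sampled voltage trace.

    Parameters
    ----------
    data : ndarray
        Samples in mV.
    fs : float
        Sampling rate in Hz.
    """

    data: np.ndarray
    fs: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 1:
            raise ValueError("LFP trace must be one-dimensional")
        if self.fs <= 0:
            raise ValueError("sampling rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.size

    @property
    def duration(self) -> float:
        """Trace duration in seconds."""
        return self.data.size / self.fs

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.data.size) / self.fs

    def copy(self) -> "LFPRecording":
        return replace(self, data=self.data.copy())


class SpeedTrace(LFPRecording):
    """Treadmill speed signal (arbitrary speed units, e.g. cm/s)."""


@dataclass
class SpikeTrain:
    """Ordered spike timestamps of one cell."""

    times: np.ndarray
    cell_id: str = ""

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        if self.times.ndim != 1:
            raise ValueError("spike times must be one-dimensional")
        if np.any(np.diff(self.times) < 0):
            self.times = np.sort(self.times)

    @property
    def n_spikes(self) -> int:
        return self.times.size

    def shift(self, dt: float) -> "SpikeTrain":
        return SpikeTrain(self.times + dt, self.cell_id)


@dataclass
class OscillationEvent:
    """A detected (or planted) transient oscillatory event.

    ``peak_time`` marks the envelope maximum; ``core_freq`` is filled in by
    the core-frequency estimators and is NaN until then.
    """

    start: float
    end: float
    peak_time: float
    peak_amplitude: float
    core_freq: float = float("nan")

    def __post_init__(self) -> None:
        if not self.end > self.start:
            raise ValueError("event must have positive duration")
        if not (self.start <= self.peak_time <= self.end):
            raise ValueError("peak_time must lie within [start, end]")

    @property
    def duration(self) -> float:
        return self.end - self.start


def validate_intervals(intervals) -> np.ndarray:
    """Return intervals as an (n, 2) array; raise if unordered or overlapping."""
    arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if np.any(arr[:, 1] <= arr[:, 0]):
        raise ValueError("intervals must have positive length")
    if arr.shape[0] > 1:
        order = np.argsort(arr[:, 0])
        arr = arr[order]
        if np.any(arr[1:, 0] < arr[:-1, 1]):
            raise ValueError("intervals overlap")
    return arr


def intervals_duration(intervals) -> float:
    """Total duration covered by a list of (start, end) intervals."""
    arr = np.asarray(intervals, dtype=float).reshape(-1, 2)
    if arr.size == 0:
        return 0.0
    return float(np.sum(arr[:, 1] - arr[:, 0]))


def in_intervals(times, intervals) -> np.ndarray:
    """Boolean mask of which ``times`` fall inside any half-open interval."""
    times = np.asarray(times, dtype=float)
    mask = np.zeros(times.shape, dtype=bool)
    for start, end in np.asarray(intervals, dtype=float).reshape(-1, 2):
        mask |= (times >= start) & (times < end)
    return mask
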