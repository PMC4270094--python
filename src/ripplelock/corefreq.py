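"""Intra-event ("core") frequency estimation.

Three estimators of the dominant oscillation frequency inside one detected
event, all operating on the band-passed (90-200 Hz) signal:

* ``zero_crossing`` — half the inverse of the mean inter-zero-crossing
  interval (two crossings per cycle), crossings located by linear
  interpolation between samples;
* ``peak_interval`` — inverse of the mean interval between neighboring
  positive local maxima;
* ``wavelet`` (default) — frequency of the global magnitude maximum of a
  complex Morlet scalogram (bandwidth parameter 5, center-frequency
  parameter 1) evaluated on a 90-200 Hz grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pywt
from scipy import signal as sps
from scipy import stats as spstats

from .core import LFPRecording, OscillationEvent, SpikeTrain

__all__ = [
    "CoreFrequencyParams",
    "CoreFrequencyComparison",
    "core_freq_zero_crossing",
    "core_freq_peak_interval",
    "core_freq_wavelet",
    "estimate_core_frequencies",
    "compare_spike_conditioned",
]

#: complex Morlet with bandwidth 5, center frequency 1 (the 'cmor5-1' wavelet)
_WAVELET = "cmor5.0-1.0"


@dataclass(frozen=True)
class CoreFrequencyParams:
    method: str = "wavelet"
    grid_low: float = 90.0
    grid_high: float = 200.0
    grid_step: float = 1.0

    def __post_init__(self) -> None:
        if self.method not in ("zero_crossing", "peak_interval", "wavelet"):
            raise ValueError(f"unknown core-frequency method {self.method!r}")
        if self.grid_step > 1.0:
            raise ValueError("wavelet grid spacing must be <= 1 Hz")

    @property
    def grid(self) -> np.ndarray:
        n = int(round((self.grid_high - self.grid_low) / self.grid_step)) + 1
        return self.grid_low + self.grid_step * np.arange(n)


def core_freq_zero_crossing(segment: np.ndarray, fs: float) -> float:
    """Half the inverse mean inter-zero-crossing interval; NaN if < 3 crossings."""
    x = np.asarray(segment, dtype=float)
    sign = np.sign(x)
    nz = np.flatnonzero(sign)
    if nz.size == 0:
        return float("nan")
    # exact-zero samples (e.g. windowed endpoints) carry the previous sign
    # so they never manufacture a crossing on their own
    prev = np.maximum.accumulate(np.where(sign != 0, np.arange(sign.size), -1))
    sign = np.where(prev >= 0, sign[np.maximum(prev, 0)], sign[nz[0]])
    flips = np.flatnonzero(sign[1:] != sign[:-1])
    if flips.size < 3:
        return float("nan")
    # linear interpolation between the samples bracketing each crossing
    t_cross = (flips + x[flips] / (x[flips] - x[flips + 1])) / fs
    return float(1.0 / np.mean(np.diff(t_cross)) / 2.0)


def core_freq_peak_interval(segment: np.ndarray, fs: float) -> float:
    """Inverse mean interval between positive local maxima; NaN if < 2 peaks."""
    x = np.asarray(segment, dtype=float)
    peaks, _ = sps.find_peaks(x, height=0.0)
    if peaks.size < 2:
        return float("nan")
    # sub-sample refinement: parabola through the peak and its neighbors
    pos = peaks.astype(float)
    inner = (peaks > 0) & (peaks < x.size - 1)
    p = peaks[inner]
    denom = x[p - 1] - 2 * x[p] + x[p + 1]
    ok = denom != 0
    pos[inner] = p + np.where(ok, 0.5 * (x[p - 1] - x[p + 1]) / np.where(ok, denom, 1.0), 0.0)
    return float(1.0 / np.mean(np.diff(pos) / fs))


def core_freq_wavelet(
    segment: np.ndarray, fs: float, params: CoreFrequencyParams = CoreFrequencyParams()
) -> float:
    """Frequency of the scalogram magnitude maximum within the segment."""
    if params.grid_high >= fs / 2:
        raise ValueError("wavelet grid exceeds Nyquist frequency")
    x = np.asarray(segment, dtype=float)
    freqs = params.grid
    fc = pywt.central_frequency(_WAVELET)  # = 1.0 for cmor*-1.0
    scales = fc * fs / freqs
    coeffs, _ = pywt.cwt(x, scales, _WAVELET, sampling_period=1.0 / fs)
    mag = np.abs(coeffs)
    row = np.unravel_index(np.argmax(mag), mag.shape)[0]
    return float(freqs[row])


def estimate_core_frequencies(
    filtered: LFPRecording,
    events: list[OscillationEvent],
    params: CoreFrequencyParams = CoreFrequencyParams(),
) -> list[OscillationEvent]:
    """Per-event core frequency on the band-passed trace.

    For the wavelet method the segment is extracted with half-event context
    padding on both sides to reduce scalogram edge effects, but the maximum
    is taken over the event span only. Returns new events with ``core_freq``
    filled in (NaN where the estimator is undefined).
    """
    out = []
    for ev in events:
        i0 = int(round(ev.start * filtered.fs))
        i1 = int(round(ev.end * filtered.fs)) + 1
        if params.method == "zero_crossing":
            f = core_freq_zero_crossing(filtered.data[i0:i1], filtered.fs)
        elif params.method == "peak_interval":
            f = core_freq_peak_interval(filtered.data[i0:i1], filtered.fs)
        else:
            pad = (i1 - i0) // 2
            j0 = max(i0 - pad, 0)
            j1 = min(i1 + pad, filtered.n_samples)
            freqs = params.grid
            scales = pywt.central_frequency(_WAVELET) * filtered.fs / freqs
            coeffs, _ = pywt.cwt(
                filtered.data[j0:j1], scales, _WAVELET, sampling_period=1.0 / filtered.fs
            )
            mag = np.abs(coeffs)[:, i0 - j0 : i1 - j0]
            f = float(freqs[np.unravel_index(np.argmax(mag), mag.shape)[0]])
        out.append(replace(ev, core_freq=f))
    return out


@dataclass
class CoreFrequencyComparison:
    """Core frequencies of events with vs without a given cell's spikes."""

    freqs_with: np.ndarray
    freqs_without: np.ndarray
    mean_with: float
    sd_with: float
    mean_without: float
    sd_without: float
    p: float
    test: str
    testable: bool


def compare_spike_conditioned(
    events: list[OscillationEvent],
    spikes: SpikeTrain,
    test: str = "mann_whitney",
) -> CoreFrequencyComparison:
    """Partition events by spike presence and compare their core frequencies.

    Default test is the two-sample rank-sum (Mann-Whitney), appropriate for
    the two independent event sets; ``wilcoxon`` (signed-rank on the sets
    truncated to equal length) is available but is not recommended for
    unpaired data. Flagged not-testable when either partition has < 2 events.
    """
    f_with, f_without = [], []
    for ev in events:
        if np.isnan(ev.core_freq):
            continue
        has = np.any((spikes.times >= ev.start) & (spikes.times <= ev.end))
        (f_with if has else f_without).append(ev.core_freq)
    f_with = np.asarray(f_with)
    f_without = np.asarray(f_without)
    testable = f_with.size >= 2 and f_without.size >= 2
    if not testable:
        p = float("nan")
    elif test == "mann_whitney":
        p = float(spstats.mannwhitneyu(f_with, f_without, alternative="two-sided").pvalue)
    elif test == "wilcoxon":
        n = min(f_with.size, f_without.size)
        p = float(spstats.wilcoxon(f_with[:n], f_without[:n]).pvalue)
    else:
        raise ValueError(f"unknown test {test!r}")

    def _ms(a: np.ndarray) -> tuple[float, float]:
        if a.size == 0:
            return float("nan"), float("nan")
        return float(a.mean()), float(a.std(ddof=1)) if a.size > 1 else 0.0

    mw, sw = _ms(f_with)
    mo, so = _ms(f_without)
    return CoreFrequencyComparison(f_with, f_without, mw, sw, mo, so, p, test, testable)
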