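"""Behavioral-state segmentation and dual-threshold event detection.

Ripple-like transients are detected on the band-passed envelope: candidate
events must exceed a high threshold (default 5 SD above the mean envelope)
and are extended outward to a lower edge threshold (default 2 SD), following
the dual-threshold convention standard in sharp-wave-ripple work. Both
thresholds are in SD units of the envelope computed within the supplied
epochs, which makes detection invariant to any rescaling of the raw trace.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import signal as sps

from .core import LFPRecording, OscillationEvent, SpeedTrace, validate_intervals
from .signal import BANDS, OscillationBand, bandpass, envelope

__all__ = [
    "BehaviorEpochs",
    "DetectionParams",
    "PeriEventWindow",
    "segment_behavior",
    "detect_events",
    "events_from_normalized_envelope",
    "peri_event_windows",
    "find_cycle_landmarks",
]


@dataclass
class BehaviorEpochs:
    """Run/rest intervals surviving the minimum-duration rule."""

    run: list
    rest: list
    speed_threshold: float
    min_run: float = 20.0
    min_rest: float = 200.0


def _state_intervals(mask: np.ndarray, fs: float) -> list[tuple[float, float]]:
    edges = np.diff(mask.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, mask.size]
    return [(s / fs, e / fs) for s, e in zip(starts, ends)]


def segment_behavior(
    speed: SpeedTrace,
    speed_threshold: float = 1.0,
    min_run: float = 20.0,
    min_rest: float = 200.0,
) -> BehaviorEpochs:
    """Threshold the speed trace into run/rest epochs and apply minimums.

    Intervals shorter than the state's minimum are discarded, not merged:
    an interrupted long rest therefore yields no rest epoch at all.
    """
    if speed.n_samples == 0:
        raise ValueError("empty speed trace")
    running = speed.data > speed_threshold
    run = [iv for iv in _state_intervals(running, speed.fs) if iv[1] - iv[0] > min_run]
    rest = [iv for iv in _state_intervals(~running, speed.fs) if iv[1] - iv[0] > min_rest]
    return BehaviorEpochs(run, rest, speed_threshold, min_run, min_rest)


@dataclass(frozen=True)
class DetectionParams:
    """Dual-threshold detector settings (thresholds in envelope SD units)."""

    band: OscillationBand = BANDS["ripple"]
    high_threshold: float = 5.0
    edge_threshold: float = 2.0
    min_duration: float = 0.02
    merge_gap: float = 0.01

    def __post_init__(self) -> None:
        if not self.high_threshold > self.edge_threshold > 0:
            raise ValueError("need high_threshold > edge_threshold > 0")


def events_from_normalized_envelope(
    z: np.ndarray, fs: float, params: DetectionParams, t0: float = 0.0
) -> list[OscillationEvent]:
    """Core thresholding on an already SD-normalized envelope.

    Contiguous spans with z >= edge_threshold that contain at least one
    sample >= high_threshold become events; events separated by less than
    ``merge_gap`` are merged; events shorter than ``min_duration`` dropped.
    """
    above = z >= params.edge_threshold
    if not above.any():
        return []
    edges = np.diff(above.astype(int))
    starts = np.flatnonzero(edges == 1) + 1
    ends = np.flatnonzero(edges == -1) + 1
    if above[0]:
        starts = np.r_[0, starts]
    if above[-1]:
        ends = np.r_[ends, above.size]
    spans = [(s, e) for s, e in zip(starts, ends) if z[s:e].max() >= params.high_threshold]
    if not spans:
        return []
    merged = [list(spans[0])]
    for s, e in spans[1:]:
        if (s - merged[-1][1]) / fs < params.merge_gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    events = []
    for s, e in merged:
        if (e - s) / fs < params.min_duration:
            continue
        peak = s + int(np.argmax(z[s:e]))
        events.append(
            OscillationEvent(
                start=t0 + s / fs,
                end=t0 + (e - 1) / fs,
                peak_time=t0 + peak / fs,
                peak_amplitude=float(z[peak]),
            )
        )
    return events


def detect_events(
    lfp: LFPRecording,
    epochs,
    params: DetectionParams = DetectionParams(),
) -> list[OscillationEvent]:
    """Detect transient oscillatory events within behavioral epochs.

    The raw trace is band-passed and envelope-detected internally; the
    envelope mean and SD are estimated from samples inside ``epochs`` only
    (event samples included — see docs for the small bias this carries), and
    the dual-threshold rule is applied per epoch. ``peak_amplitude`` is
    reported in SD units.
    """
    epochs = validate_intervals(epochs)
    if epochs[:, 0].min() < 0 or epochs[:, 1].max() > lfp.duration + 1.0 / lfp.fs:
        raise ValueError("epochs extend outside the trace")
    env = envelope(bandpass(lfp, params.band)).data
    sample_mask = np.zeros(env.size, dtype=bool)
    bounds = []
    for start, end in epochs:
        i0 = int(round(start * lfp.fs))
        i1 = min(int(round(end * lfp.fs)), env.size)
        sample_mask[i0:i1] = True
        bounds.append((i0, i1))
    mu = env[sample_mask].mean()
    sd = env[sample_mask].std()
    if sd == 0:
        return []
    events: list[OscillationEvent] = []
    for i0, i1 in bounds:
        z = (env[i0:i1] - mu) / sd
        events.extend(events_from_normalized_envelope(z, lfp.fs, params, t0=i0 / lfp.fs))
    return sorted(events, key=lambda e: e.start)


@dataclass
class PeriEventWindow:
    """Before/during/after spans of one event; flanks last 2x its duration."""

    before: tuple[float, float]
    during: tuple[float, float]
    after: tuple[float, float]
    truncated_before: bool = False
    truncated_after: bool = False
    overlaps_neighbor: bool = False


def peri_event_windows(
    events: list[OscillationEvent], trace_duration: float | None = None
) -> list[PeriEventWindow]:
    """Peri-event windows: flanks of twice the event duration on each side.

    Windows running past the trace edges are truncated and flagged; windows
    overlapping a neighboring event's span are kept but flagged.
    """
    windows = []
    for i, ev in enumerate(events):
        d = ev.duration
        b0, a1 = ev.start - 2 * d, ev.end + 2 * d
        trunc_b = b0 < 0
        trunc_a = trace_duration is not None and a1 > trace_duration
        overlaps = (i > 0 and b0 < events[i - 1].end) or (
            i + 1 < len(events) and a1 > events[i + 1].start
        )
        windows.append(
            PeriEventWindow(
                before=(max(b0, 0.0), ev.start),
                during=(ev.start, ev.end),
                after=(ev.end, min(a1, trace_duration) if trunc_a else a1),
                truncated_before=trunc_b,
                truncated_after=bool(trunc_a),
                overlaps_neighbor=overlaps,
            )
        )
    return windows


def find_cycle_landmarks(filtered: LFPRecording) -> tuple[np.ndarray, np.ndarray]:
    """Trough and peak times of a band-passed trace, strictly interleaved.

    Local extrema are found on the filtered signal; where two extrema of the
    same kind occur in a row (possible in noise), the more extreme one is
    kept so that troughs and peaks alternate.
    """
    x = filtered.data
    peaks, _ = sps.find_peaks(x)
    troughs, _ = sps.find_peaks(-x)
    # one-sided extrema at the trace edges (e.g. a trace starting exactly at
    # a trough); accepted only when at least as extreme as every interior
    # landmark of the same kind, so a cycle cut off mid-limb adds nothing
    if x.size >= 2:
        t_floor = x[troughs].min() if troughs.size else np.inf
        p_ceil = x[peaks].max() if peaks.size else -np.inf
        if x[0] < x[1] and x[0] <= t_floor:
            troughs = np.r_[0, troughs]
        elif x[0] > x[1] and x[0] >= p_ceil:
            peaks = np.r_[0, peaks]
        if x[-1] < x[-2] and x[-1] <= t_floor:
            troughs = np.r_[troughs, x.size - 1]
        elif x[-1] > x[-2] and x[-1] >= p_ceil:
            peaks = np.r_[peaks, x.size - 1]
    if peaks.size == 0 or troughs.size == 0:
        return troughs / filtered.fs, peaks / filtered.fs
    # merge and de-duplicate runs of same-kind extrema
    idx = np.concatenate([troughs, peaks])
    kind = np.concatenate([np.zeros(troughs.size, int), np.ones(peaks.size, int)])
    order = np.argsort(idx)
    idx, kind = idx[order], kind[order]
    keep_idx: list[int] = [idx[0]]
    keep_kind: list[int] = [kind[0]]
    for i, k in zip(idx[1:], kind[1:]):
        if k == keep_kind[-1]:
            better = (x[i] > x[keep_idx[-1]]) if k == 1 else (x[i] < x[keep_idx[-1]])
            if better:
                keep_idx[-1] = i
        else:
            keep_idx.append(i)
            keep_kind.append(k)
    keep_idx = np.asarray(keep_idx)
    keep_kind = np.asarray(keep_kind)
    return keep_idx[keep_kind == 0] / filtered.fs, keep_idx[keep_kind == 1] / filtered.fs
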