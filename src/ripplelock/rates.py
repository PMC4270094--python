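"""Firing-rate analysis around transient events.

Includes the Monte-Carlo randomization tests used to decide whether a cell's
firing is significantly modulated by events: either the spike times are
redrawn uniformly within the behavioral state (spike shuffle) or the events
are repositioned within it (event shuffle), and the observed in-event rate
is compared to the surrogate distribution with a two-sided
``(k + 1) / (N + 1)`` p-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import (
    LFPRecording,
    OscillationEvent,
    SpikeTrain,
    in_intervals,
    intervals_duration,
    validate_intervals,
)
from .detect import PeriEventWindow, find_cycle_landmarks

__all__ = [
    "RateModulationResult",
    "PeriEventHistogram",
    "firing_rate",
    "event_rate_modulation",
    "participation_fraction",
    "early_spike_fraction",
    "detect_doublets",
    "peri_event_histogram",
]


def firing_rate(spikes: SpikeTrain, intervals) -> float:
    """Mean firing rate (Hz) within a set of intervals."""
    total = intervals_duration(intervals)
    if total <= 0:
        raise ValueError("total interval duration must be positive")
    return float(np.count_nonzero(in_intervals(spikes.times, intervals)) / total)


@dataclass
class RateModulationResult:
    rate_in: float
    rate_out: float
    p: float
    direction: str  # 'increase' | 'decrease' | 'none'
    n_surrogates: int
    seed: int
    mode: str = "spike_shuffle"


def _concat_coords(intervals: np.ndarray):
    """Map absolute times onto the concatenated state-interval line."""
    durs = intervals[:, 1] - intervals[:, 0]
    offsets = np.r_[0.0, np.cumsum(durs)]

    def to_line(times: np.ndarray) -> np.ndarray:
        out = np.full(np.asarray(times, float).shape, np.nan)
        for (s, e), off in zip(intervals, offsets):
            m = (times >= s) & (times < e)
            out[m] = times[m] - s + off
        return out

    return to_line, float(offsets[-1])


def event_rate_modulation(
    spikes: SpikeTrain,
    events: list[OscillationEvent],
    state_intervals,
    mode: str = "spike_shuffle",
    n_surrogates: int = 1000,
    seed: int = 0,
    alpha: float = 0.05,
) -> RateModulationResult:
    """Monte-Carlo test of in-event vs out-of-event firing.

    The test statistic is the in-event spike count. Surrogates redraw spike
    times uniformly within the state intervals (``spike_shuffle``) or
    uniformly reposition the events within them preserving durations and
    non-overlap (``event_shuffle``). The two-sided p doubles the more
    extreme tail's ``(k + 1)/(N + 1)`` value, capped at 1.
    """
    if n_surrogates < 100:
        raise ValueError("fewer than 100 surrogates is underpowered")
    if mode not in ("spike_shuffle", "event_shuffle"):
        raise ValueError(f"unknown mode {mode!r}")
    intervals = validate_intervals(state_intervals)
    if not events:
        raise ValueError("need at least one event")
    ev_arr = np.array([[e.start, e.end] for e in events], dtype=float)
    inside = in_intervals(ev_arr[:, 0], intervals) & in_intervals(
        ev_arr[:, 1] - 1e-9, intervals
    )
    if not inside.all():
        raise ValueError("events must lie within the state intervals")
    to_line, total = _concat_coords(intervals)
    spike_line = to_line(spikes.times)
    spike_line = np.sort(spike_line[~np.isnan(spike_line)])
    starts_line = to_line(ev_arr[:, 0])
    order = np.argsort(starts_line)
    ev_starts = starts_line[order]
    ev_durs = (ev_arr[:, 1] - ev_arr[:, 0])[order]
    ev_ends = ev_starts + ev_durs
    in_dur = float(ev_durs.sum())
    out_dur = total - in_dur

    def count_in(sp: np.ndarray, starts: np.ndarray, ends: np.ndarray) -> int:
        i0 = np.searchsorted(sp, starts, side="left")
        i1 = np.searchsorted(sp, ends, side="right")
        return int(np.sum(i1 - i0))

    obs = count_in(spike_line, ev_starts, ev_ends)
    rate_in = obs / in_dur if in_dur > 0 else float("nan")
    rate_out = (spike_line.size - obs) / out_dur if out_dur > 0 else float("nan")

    rng = np.random.default_rng(seed)
    n = spike_line.size
    surr = np.empty(n_surrogates, dtype=int)
    if mode == "spike_shuffle":
        for i in range(n_surrogates):
            sp = np.sort(rng.uniform(0.0, total, n))
            surr[i] = count_in(sp, ev_starts, ev_ends)
    else:
        slack = total - ev_durs.sum()
        if slack <= 0:
            raise ValueError("events fill the state intervals; cannot shuffle them")
        cum = np.r_[0.0, np.cumsum(ev_durs[:-1])]
        for i in range(n_surrogates):
            u = np.sort(rng.uniform(0.0, slack, ev_durs.size))
            starts = u + cum
            surr[i] = count_in(spike_line, starts, starts + ev_durs)

    k_hi = int(np.sum(surr >= obs))
    k_lo = int(np.sum(surr <= obs))
    p_hi = (k_hi + 1) / (n_surrogates + 1)
    p_lo = (k_lo + 1) / (n_surrogates + 1)
    p = min(1.0, 2.0 * min(p_hi, p_lo))
    if p >= alpha:
        direction = "none"
    else:
        direction = "increase" if p_hi < p_lo else "decrease"
    return RateModulationResult(rate_in, rate_out, p, direction, n_surrogates, seed, mode)


def participation_fraction(spikes: SpikeTrain, events: list[OscillationEvent]) -> float:
    """Fraction of events containing at least one spike."""
    if not events:
        raise ValueError("need at least one event")
    hits = sum(
        1
        for ev in events
        if np.any((spikes.times >= ev.start) & (spikes.times <= ev.end))
    )
    return hits / len(events)


def early_spike_fraction(spikes: SpikeTrain, events: list[OscillationEvent]) -> float:
    """Fraction of in-event spikes fired before the envelope peak.

    Pooled over events; returns NaN when no event contains a spike.
    """
    early = total = 0
    for ev in events:
        m = (spikes.times >= ev.start) & (spikes.times <= ev.end)
        total += int(np.count_nonzero(m))
        early += int(np.count_nonzero(m & (spikes.times < ev.peak_time)))
    if total == 0:
        return float("nan")
    return early / total


def detect_doublets(
    spikes: SpikeTrain,
    events: list[OscillationEvent],
    ripple_filtered: LFPRecording,
) -> tuple[float, float]:
    """Doublet firing during events.

    A doublet is >= 2 spikes between two consecutive troughs of the
    band-passed trace inside one event. Returns (fraction of events with at
    least one doublet, mean intra-event firing rate in Hz).
    """
    if not events:
        raise ValueError("need at least one event")
    troughs, _ = find_cycle_landmarks(ripple_filtered)
    n_doublet_events = 0
    n_spikes_in = 0
    dur_in = 0.0
    for ev in events:
        cyc = troughs[(troughs >= ev.start) & (troughs <= ev.end)]
        sp = spikes.times[(spikes.times >= ev.start) & (spikes.times <= ev.end)]
        n_spikes_in += sp.size
        dur_in += ev.duration
        if cyc.size >= 2 and sp.size >= 2:
            counts, _ = np.histogram(sp, bins=cyc)
            if np.any(counts >= 2):
                n_doublet_events += 1
    rate = n_spikes_in / dur_in if dur_in > 0 else float("nan")
    return n_doublet_events / len(events), float(rate)


@dataclass
class PeriEventHistogram:
    """Normalized-time peri-event spike histogram (40 + 20 + 40 bins).

    ``probs[b]`` is the mean spike count per event in bin ``b``, where each
    event's before/during/after span is divided into 40/20/40 equal bins of
    its own duration. For the short bins this is in practice the per-bin
    spiking probability. By construction, summing the 20 'during' bins gives
    the mean in-event spike count per event.
    """

    probs: np.ndarray  # shape (100,)
    n_events: int
    bins = (40, 20, 40)


def peri_event_histogram(
    spikes: SpikeTrain, windows: list[PeriEventWindow]
) -> PeriEventHistogram:
    """Spiking probability in normalized time before/during/after events."""
    if not windows:
        raise ValueError("need at least one event window")
    acc = np.zeros(100)
    for w in windows:
        for span, n_bins, off in ((w.before, 40, 0), (w.during, 20, 40), (w.after, 40, 60)):
            s, e = span
            if e <= s:
                continue
            m = (spikes.times >= s) & (spikes.times < e)
            if not m.any():
                continue
            frac = (spikes.times[m] - s) / (e - s)
            idx = np.minimum((frac * n_bins).astype(int), n_bins - 1)
            np.add.at(acc, off + idx, 1.0)
    return PeriEventHistogram(acc / len(windows), len(windows))
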