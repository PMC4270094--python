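"""Synthetic LFP, speed and spike-train generation with known ground truth.

The generator emulates the statistical structure the analysis pipeline
assumes: 1/f-background LFP, theta epochs with theta-phase-coupled fast
(epsilon-band) power, transient ripple-like events with a configurable core
frequency, and spike trains that are von-Mises phase-locked with a known
preferred phase and concentration, optionally rate-gated inside events and
firing within-cycle doublets. Everything is deterministic given a seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import i0e

from .core import LFPRecording, SpeedTrace, SpikeTrain, validate_intervals

__all__ = [
    "SimConfig",
    "Coupling",
    "PlantedRhythm",
    "PlantedEvent",
    "SpikeModel",
    "GroundTruth",
    "generate_background_lfp",
    "plant_rhythms",
    "plant_events",
    "generate_spikes",
    "generate_speed_trace",
    "von_mises_rate_factor",
]


@dataclass(frozen=True)
class SimConfig:
    """Background-trace configuration.

    ``noise_exponent`` is the 1/f^alpha spectral slope of the Gaussian
    background; ``noise_scale`` its RMS amplitude in mV.
    """

    duration: float
    fs: float = 1250.0
    seed: int = 0
    noise_exponent: float = 1.0
    noise_scale: float = 0.05

    def __post_init__(self) -> None:
        if self.duration <= 0:
            raise ValueError("duration must be positive")
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if self.noise_scale < 0:
            raise ValueError("noise_scale must be non-negative")


@dataclass(frozen=True)
class Coupling:
    """Cross-frequency coupling of a fast rhythm to a slower carrier.

    The fast rhythm's amplitude is maximal when the carrier is at
    ``preferred_carrier_phase`` (degrees, 0 = carrier trough) and is reduced
    by up to ``modulation_depth`` (0..1) half a carrier cycle away.
    """

    carrier_band: str
    preferred_carrier_phase: float
    modulation_depth: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.modulation_depth <= 1.0:
            raise ValueError("modulation_depth must be in [0, 1]")


@dataclass
class PlantedRhythm:
    """A continuous oscillation confined to epochs of the trace."""

    band_name: str
    center_freq: float
    amplitude: float
    epoch_intervals: list
    coupling: Coupling | None = None


@dataclass
class PlantedEvent:
    """A transient amplitude-enveloped oscillation burst."""

    start: float
    duration: float
    core_freq: float
    peak_amplitude: float
    envelope_shape: str = "hann"

    @property
    def end(self) -> float:
        return self.start + self.duration

    def envelope(self, t: np.ndarray) -> np.ndarray:
        """Envelope (0..1) evaluated at absolute times ``t``."""
        x = (t - self.start) / self.duration
        if self.envelope_shape == "hann":
            w = 0.5 * (1.0 - np.cos(2.0 * np.pi * np.clip(x, 0.0, 1.0)))
        elif self.envelope_shape == "rect":
            w = np.ones_like(x)
        else:
            raise ValueError(f"unknown envelope shape {self.envelope_shape!r}")
        w[(x < 0) | (x > 1)] = 0.0
        return w

    def phase_deg(self, t: np.ndarray) -> np.ndarray:
        """Intra-event oscillation phase (0 deg = trough) at times ``t``."""
        return (360.0 * self.core_freq * (np.asarray(t) - self.start)) % 360.0

    def threshold_crossings(self, level: float) -> tuple[float, float]:
        """Times where ``peak_amplitude * envelope`` crosses ``level``.

        Only defined for the Hann envelope; used to predict where a
        dual-threshold detector should place event boundaries.
        """
        if self.envelope_shape != "hann":
            raise ValueError("analytic crossings only available for Hann envelope")
        q = level / self.peak_amplitude
        if not 0 < q < 1:
            raise ValueError("level must be between 0 and the peak amplitude")
        x = self.duration / (2.0 * np.pi) * np.arccos(1.0 - 2.0 * q)
        return self.start + x, self.end - x


@dataclass(frozen=True)
class SpikeModel:
    """Ground-truth spiking model of one cell.

    The instantaneous rate is ``base_rate`` multiplied by a von-Mises factor
    of the oscillation phase (normalized to unit mean over uniform phase) and
    by ``event_gain`` inside events. ``doublet_prob`` is the probability, per
    event cycle containing a spike, of a second spike 3-5 ms after the first.
    """

    base_rate: float
    preferred_phase: float = 0.0
    kappa: float = 0.0
    event_gain: float = 1.0
    doublet_prob: float = 0.0
    refractory: float = 0.002

    def __post_init__(self) -> None:
        if self.base_rate < 0 or self.kappa < 0 or self.event_gain < 0:
            raise ValueError("rates, kappa and event_gain must be non-negative")
        if not 0.0 <= self.doublet_prob <= 1.0:
            raise ValueError("doublet_prob must be in [0, 1]")
        if not np.isfinite(self.base_rate) or not np.isfinite(self.kappa):
            raise ValueError("base_rate and kappa must be finite")


@dataclass
class GroundTruth:
    """Everything the generator knows that the analysis must recover."""

    fs: float = 0.0
    events: list = field(default_factory=list)  # list[PlantedEvent]
    phases: dict = field(default_factory=dict)  # band name -> phase (deg) per sample
    cells: dict = field(default_factory=dict)  # cell id -> SpikeModel
    extra: dict = field(default_factory=dict)

    def merge(self, other: "GroundTruth") -> "GroundTruth":
        out = GroundTruth(self.fs or other.fs, list(self.events), dict(self.phases),
                          dict(self.cells), dict(self.extra))
        out.events += other.events
        out.phases.update(other.phases)
        out.cells.update(other.cells)
        out.extra.update(other.extra)
        return out

    # -- serialization (plain-python payload; YAML round-trips repr floats exactly)

    def to_dict(self) -> dict:
        def plain(obj):
            if isinstance(obj, dict):
                return {k: plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [plain(v) for v in obj]
            if isinstance(obj, np.ndarray):
                return obj.astype(float).tolist()
            if isinstance(obj, (np.floating, float)):
                return float(obj)
            if isinstance(obj, (np.integer, int)):
                return int(obj)
            return obj

        return plain(
            {
                "fs": self.fs,
                "events": [asdict(e) for e in self.events],
                "phases": {k: np.asarray(v, dtype=float) for k, v in self.phases.items()},
                "cells": {k: asdict(m) for k, m in self.cells.items()},
                "extra": self.extra,
            }
        )

    @classmethod
    def from_dict(cls, d: dict) -> "GroundTruth":
        return cls(
            fs=float(d.get("fs", 0.0)),
            events=[PlantedEvent(**e) for e in d.get("events", [])],
            phases={k: np.asarray(v, dtype=float) for k, v in d.get("phases", {}).items()},
            cells={k: SpikeModel(**m) for k, m in d.get("cells", {}).items()},
            extra=d.get("extra", {}),
        )


def generate_background_lfp(config: SimConfig) -> LFPRecording:
    """Spectrally shaped (1/f^alpha) Gaussian background noise.

    Shaped in the frequency domain: white Gaussian noise is filtered by
    ``f^(-alpha/2)`` (power slope -alpha) and rescaled to ``noise_scale`` RMS.
    """
    n = int(round(config.duration * config.fs))
    if n < 2:
        raise ValueError("duration too short for the requested sampling rate")
    rng = np.random.default_rng(config.seed)
    white = rng.standard_normal(n)
    if config.noise_scale == 0:
        return LFPRecording(np.zeros(n), config.fs)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / config.fs)
    shaping = np.ones_like(freqs)
    nz = freqs > 0
    shaping[nz] = freqs[nz] ** (-config.noise_exponent / 2.0)
    shaping[0] = 0.0  # no DC
    data = np.fft.irfft(spec * shaping, n=n)
    data *= config.noise_scale / data.std()
    return LFPRecording(data, config.fs)


def plant_rhythms(
    lfp: LFPRecording, rhythms: list[PlantedRhythm], seed: int | None = None
) -> tuple[LFPRecording, GroundTruth]:
    """Add continuous oscillations (optionally cross-frequency coupled).

    Each rhythm contributes ``amplitude * (-cos(phase))`` within its epochs,
    so phase 0 deg is the waveform trough. A coupled rhythm's amplitude is
    modulated by the phase of an earlier rhythm in the list (its carrier).
    Returns the modified trace and the ground-truth phase series per rhythm
    (NaN outside that rhythm's epochs).
    """
    out = lfp.copy()
    gt = GroundTruth(fs=lfp.fs)
    t = lfp.times
    for rhythm in rhythms:
        if rhythm.center_freq >= lfp.fs / 2:
            raise ValueError(f"rhythm {rhythm.band_name}: frequency above Nyquist")
        epochs = validate_intervals(rhythm.epoch_intervals)
        if epochs[:, 0].min() < 0 or epochs[:, 1].max() > lfp.duration + 1e-9:
            raise ValueError(f"rhythm {rhythm.band_name}: epochs outside trace")
        phase = np.full(t.size, np.nan)
        for start, end in epochs:
            i0_, i1 = int(round(start * lfp.fs)), int(round(end * lfp.fs))
            phase[i0_:i1] = (360.0 * rhythm.center_freq * (t[i0_:i1] - start)) % 360.0
        amp = np.where(np.isnan(phase), 0.0, rhythm.amplitude)
        if rhythm.coupling is not None:
            c = rhythm.coupling
            if c.carrier_band not in gt.phases:
                raise ValueError(
                    f"carrier {c.carrier_band!r} must be planted before {rhythm.band_name!r}"
                )
            carrier = gt.phases[c.carrier_band]
            mod = (1.0 - c.modulation_depth) + c.modulation_depth * 0.5 * (
                1.0 + np.cos(np.deg2rad(carrier - c.preferred_carrier_phase))
            )
            amp = amp * np.where(np.isnan(mod), 0.0, mod)
        wave = np.where(np.isnan(phase), 0.0, -np.cos(np.deg2rad(phase)))
        out.data += amp * wave
        gt.phases[rhythm.band_name] = phase
    return out, gt


def plant_events(
    lfp: LFPRecording, events: list[PlantedEvent]
) -> tuple[LFPRecording, GroundTruth]:
    """Add amplitude-enveloped oscillation bursts (ripple surrogates).

    Events must lie within the trace and must not overlap. Each contributes
    ``peak_amplitude * envelope(t) * (-cos(intra-event phase))``.
    """
    arr = sorted(events, key=lambda e: e.start)
    for a, b in zip(arr, arr[1:]):
        if b.start < a.end:
            raise ValueError("planted events overlap")
    out = lfp.copy()
    t = lfp.times
    for ev in arr:
        if ev.start < 0 or ev.end > lfp.duration + 1e-9:
            raise ValueError("event outside trace")
        i0_ = int(np.floor(ev.start * lfp.fs))
        i1 = min(int(np.ceil(ev.end * lfp.fs)) + 1, t.size)
        seg_t = t[i0_:i1]
        out.data[i0_:i1] += (
            ev.peak_amplitude * ev.envelope(seg_t) * -np.cos(np.deg2rad(ev.phase_deg(seg_t)))
        )
    return out, GroundTruth(fs=lfp.fs, events=list(arr))


def von_mises_rate_factor(phase_deg: np.ndarray, preferred_deg: float, kappa: float) -> np.ndarray:
    """Von-Mises rate modulation normalized to unit mean over uniform phase.

    Computed as exp(kappa*(cos(theta)-1)) / (exp(-kappa)*I0(kappa)) with the
    exponentially scaled Bessel function, stable for arbitrarily large kappa.
    """
    theta = np.deg2rad(np.asarray(phase_deg, dtype=float) - preferred_deg)
    return np.exp(kappa * (np.cos(theta) - 1.0)) / i0e(kappa)


def _thin_rate(rate: np.ndarray, fs: float, rng: np.random.Generator, refractory: float) -> np.ndarray:
    """Bernoulli thinning of a per-sample rate with a dead-time constraint.

    Returns spike times at sample resolution.
    """
    p = np.clip(rate / fs, 0.0, 0.95)
    hits = np.flatnonzero(rng.random(p.size) < p)
    if hits.size == 0:
        return np.array([])
    min_gap = refractory * fs
    kept = [hits[0]]
    for h in hits[1:]:
        if h - kept[-1] >= min_gap:
            kept.append(h)
    return np.asarray(kept, dtype=float) / fs


def _insert_doublets(
    times: np.ndarray,
    events: list[PlantedEvent],
    prob: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Per event cycle containing a spike, add a trailing spike 3-5 ms later
    with probability ``prob`` (kept inside the event)."""
    if prob <= 0 or not events:
        return times
    extra = []
    for ev in events:
        in_ev = times[(times >= ev.start) & (times < ev.end)]
        if in_ev.size == 0:
            continue
        period = 1.0 / ev.core_freq
        cycles = np.floor((in_ev - ev.start) / period).astype(int)
        for cyc in np.unique(cycles):
            first = in_ev[cycles == cyc].min()
            if rng.random() < prob:
                t2 = first + rng.uniform(0.003, 0.005)
                if t2 < ev.end:
                    extra.append(t2)
    if not extra:
        return times
    return np.sort(np.concatenate([times, extra]))


def generate_spikes(
    phase_series: np.ndarray | None,
    fs: float,
    model: SpikeModel,
    events: list[PlantedEvent] = (),
    seed: int = 0,
    n_samples: int | None = None,
    cell_id: str = "",
) -> SpikeTrain:
    """Inhomogeneous phase-locked point process by thinning.

    ``phase_series`` gives the oscillation phase (deg) per sample, NaN where
    no rhythm is defined (rate falls back to ``base_rate`` there); pass None
    for a homogeneous train. Inside ``events`` the rate is multiplied by
    ``model.event_gain`` and doublets are inserted per event cycle.
    """
    if phase_series is None:
        if n_samples is None:
            raise ValueError("n_samples required when phase_series is None")
        rate = np.full(int(n_samples), float(model.base_rate))
    else:
        phase_series = np.asarray(phase_series, dtype=float)
        factor = np.ones(phase_series.size)
        valid = ~np.isnan(phase_series)
        factor[valid] = von_mises_rate_factor(
            phase_series[valid], model.preferred_phase, model.kappa
        )
        rate = model.base_rate * factor
    if events:
        t = np.arange(rate.size) / fs
        for ev in events:
            inside = (t >= ev.start) & (t < ev.end)
            rate[inside] *= model.event_gain
    rng = np.random.default_rng(seed)
    times = _thin_rate(rate, fs, rng, model.refractory)
    times = _insert_doublets(times, list(events), model.doublet_prob, rng)
    return SpikeTrain(times, cell_id)


def generate_speed_trace(
    segments: list[tuple[str, float]],
    fs: float = 50.0,
    run_speed: float = 10.0,
    rest_speed: float = 0.0,
) -> SpeedTrace:
    """Piecewise-constant speed signal from (state, duration) segments.

    States are 'run' or 'rest'; run segments sit at ``run_speed`` (above any
    sensible threshold), rest segments at ``rest_speed``.
    """
    chunks = []
    for state, dur in segments:
        if dur <= 0:
            raise ValueError("segment durations must be positive")
        if state not in ("run", "rest"):
            raise ValueError(f"unknown state {state!r}")
        level = run_speed if state == "run" else rest_speed
        chunks.append(np.full(int(round(dur * fs)), float(level)))
    if not chunks:
        raise ValueError("at least one segment required")
    return SpeedTrace(np.concatenate(chunks), fs)
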