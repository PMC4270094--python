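"""High-level synthetic recording sessions.

These builders compose the low-level generators into complete datasets —
background LFP with planted oscillations/events, a speed trace, and a cohort
of phase-locked spike trains — calibrated so that planted event amplitudes
are expressed in SD units of the background's ripple-band envelope (the
detector's own units).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .core import LFPRecording, SpeedTrace, SpikeTrain
from .signal import BANDS, bandpass, envelope
from .synth import (
    Coupling,
    GroundTruth,
    PlantedEvent,
    PlantedRhythm,
    SimConfig,
    SpikeModel,
    _insert_doublets,
    _thin_rate,
    generate_background_lfp,
    generate_speed_trace,
    generate_spikes,
    plant_events,
    plant_rhythms,
    von_mises_rate_factor,
)

__all__ = ["CellSpec", "Session", "place_events", "ripple_session", "cohort_session"]


@dataclass(frozen=True)
class CellSpec:
    """Ground-truth firing program of one simulated cell.

    Theta parameters apply during running; event parameters apply inside
    planted fast events during rest (the rest baseline is ``rate_rest``).
    """

    cell_id: str
    sub_class: str = ""
    rate_run: float = 25.0
    theta_phase: float = 0.0
    theta_kappa: float = 1.0
    rate_rest: float = 10.0
    event_phase: float = 0.0
    event_kappa: float = 2.0
    event_gain: float = 4.0
    doublet_prob: float = 0.0
    refractory: float = 0.002

    @property
    def cell_class(self) -> str:
        return self.sub_class.split("-", 1)[-1] if self.sub_class else ""


@dataclass
class Session:
    """A complete synthetic recording: signals, spikes and the truth."""

    lfp: LFPRecording
    speed: SpeedTrace
    spikes: dict[str, SpikeTrain]
    ground_truth: GroundTruth
    run_intervals: list
    rest_intervals: list

    def predicted_boundaries(self, edge_threshold: float = 2.0) -> list[tuple[float, float]]:
        """Where a dual-threshold detector should place each event's edges.

        Solves ``amp * hann(t) = level`` for the envelope level equivalent to
        ``mean + edge_threshold * SD`` of the detection-time envelope, after
        removing the background floor in quadrature (the combined envelope of
        tone + independent noise is approximately the root sum of squares).
        """
        x = self.ground_truth.extra
        tau = x["det_env_mean"] + edge_threshold * x["det_env_sd"]
        level = np.sqrt(max(tau**2 - x["noise_env_ms"], 1e-12))
        out = []
        amps = x.get("event_env_amp")
        for i, ev in enumerate(self.ground_truth.events):
            # effective in-band amplitude (raw amplitude was pre-compensated
            # for the detection filter's response at the core frequency)
            amp = amps[i] if amps is not None else ev.peak_amplitude
            q = level / amp
            d = ev.duration
            xq = d / (2.0 * np.pi) * np.arccos(1.0 - 2.0 * q)
            out.append((ev.start + xq, ev.end - xq))
        return out


def place_events(
    n_events: int,
    interval: tuple[float, float],
    rng: np.random.Generator,
    duration_range: tuple[float, float] = (0.04, 0.15),
    freq_range: tuple[float, float] = (90.0, 200.0),
    gap: float = 1.0,
    margin: float = 1.0,
    peak_amplitude: float = 1.0,
) -> list[PlantedEvent]:
    """Random non-overlapping Hann-enveloped events within an interval."""
    lo, hi = interval
    durs = rng.uniform(*duration_range, n_events)
    freqs = rng.uniform(*freq_range, n_events)
    slack = (hi - lo) - 2 * margin - float(durs.sum()) - gap * (n_events - 1)
    if slack < 0:
        raise ValueError("interval too short for the requested events")
    offsets = np.sort(rng.uniform(0.0, slack, n_events))
    starts = lo + margin + offsets + np.r_[0.0, np.cumsum(durs[:-1] + gap)]
    return [
        PlantedEvent(float(s), float(d), float(f), peak_amplitude)
        for s, d, f in zip(starts, durs, freqs)
    ]


def _event_phase_series(events: list[PlantedEvent], n: int, fs: float) -> np.ndarray:
    """Intra-event oscillation phase per sample; NaN outside events."""
    phase = np.full(n, np.nan)
    t = np.arange(n) / fs
    for ev in events:
        m = (t >= ev.start) & (t < ev.end)
        phase[m] = ev.phase_deg(t[m])
    return phase


def _bandpass_gain(freqs: np.ndarray, fs: float, order: int = 4) -> np.ndarray:
    """Amplitude response of the zero-phase ripple-band filter at ``freqs``."""
    from scipy import signal as sps

    band = BANDS["ripple"]
    sos = sps.butter(order, [band.low, band.high], btype="bandpass", fs=fs, output="sos")
    _, h = sps.sosfreqz(sos, worN=np.atleast_1d(freqs), fs=fs)
    return np.abs(h) ** 2  # forward-backward squares the magnitude response


def _calibrated_events(
    background: LFPRecording,
    rest: tuple[float, float],
    n_events: int,
    snr: float,
    rng: np.random.Generator,
    duration_range=(0.04, 0.15),
    freq_range=(90.0, 200.0),
) -> tuple[list[PlantedEvent], dict]:
    """Place events whose in-band envelope peaks at ``mean + snr * SD`` of
    the background ripple-band envelope within the rest interval.

    The planted raw amplitude is boosted by the inverse of the detection
    filter's response at the event's core frequency, so the SD level is
    reached in the detector's own (band-passed) units even at the band
    corners where a Butterworth response is -3 dB per pass.
    """
    env = envelope(bandpass(background, BANDS["ripple"])).data
    i0, i1 = int(rest[0] * background.fs), int(rest[1] * background.fs)
    mu0, sd0 = float(env[i0:i1].mean()), float(env[i0:i1].std())
    amp = mu0 + snr * sd0
    events = place_events(
        n_events, rest, rng, duration_range, freq_range, peak_amplitude=amp
    )
    gains = _bandpass_gain(np.array([ev.core_freq for ev in events]), background.fs)

    def _with_amp(target: float) -> list[PlantedEvent]:
        return [
            PlantedEvent(ev.start, ev.duration, ev.core_freq, target / g, ev.envelope_shape)
            for ev, g in zip(events, gains)
        ]

    # second calibration pass: the detector's SD includes the event samples,
    # so re-express the target level in detection-time envelope units
    planted, _ = plant_events(background, _with_amp(amp))
    mu_d, sd_d = _detection_env_stats(planted, rest)
    amp = mu_d + snr * sd_d
    stats = {
        "noise_env_mean": mu0,
        "noise_env_sd": sd0,
        "noise_env_ms": mu0**2 + sd0**2,
        "event_env_amp": [amp] * n_events,
    }
    return _with_amp(amp), stats


def _detection_env_stats(lfp: LFPRecording, rest: tuple[float, float]) -> tuple[float, float]:
    env = envelope(bandpass(lfp, BANDS["ripple"])).data
    i0, i1 = int(rest[0] * lfp.fs), int(rest[1] * lfp.fs)
    return float(env[i0:i1].mean()), float(env[i0:i1].std())


def ripple_session(
    seed: int,
    rest_duration: float = 300.0,
    fs: float = 1250.0,
    n_events: int = 20,
    snr: float = 8.0,
    duration_range: tuple[float, float] = (0.04, 0.15),
    freq_range: tuple[float, float] = (90.0, 200.0),
    cells: list[CellSpec] = (),
    noise_exponent: float = 1.0,
    noise_scale: float = 0.05,
) -> Session:
    """Rest-only session: 1/f background plus planted ripple-like events.

    ``snr`` is the planted peak envelope amplitude in background ripple-band
    envelope SD units above the envelope mean.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2025]))
    cfg = SimConfig(rest_duration, fs, seed, noise_exponent, noise_scale)
    background = generate_background_lfp(cfg)
    rest = (0.0, rest_duration)
    events, stats = _calibrated_events(
        background, rest, n_events, snr, rng, duration_range, freq_range
    )
    lfp, gt = plant_events(background, events)
    gt.extra.update(stats)
    mu_d, sd_d = _detection_env_stats(lfp, rest)
    gt.extra.update({"det_env_mean": mu_d, "det_env_sd": sd_d})
    speed = generate_speed_trace([("rest", rest_duration)])
    phase = _event_phase_series(events, lfp.n_samples, fs)
    spikes: dict[str, SpikeTrain] = {}
    for i, spec in enumerate(cells):
        model = SpikeModel(
            spec.rate_rest,
            spec.event_phase,
            spec.event_kappa,
            spec.event_gain,
            spec.doublet_prob,
            spec.refractory,
        )
        sub_seed = int(np.random.SeedSequence([seed, 7, i]).generate_state(1)[0] % (2**31))
        spikes[spec.cell_id] = generate_spikes(
            phase, fs, model, events, seed=sub_seed, cell_id=spec.cell_id
        )
        gt.cells[spec.cell_id] = model
    return Session(lfp, speed, spikes, gt, [], [rest])


def cohort_session(
    seed: int,
    cells: list[CellSpec],
    run_duration: float = 30.0,
    rest_duration: float = 220.0,
    fs: float = 1250.0,
    n_events: int = 40,
    snr: float = 8.0,
    theta_freq: float = 8.0,
    theta_amplitude: float = 0.2,
    epsilon_coupling: Coupling | None = None,
    noise_exponent: float = 1.0,
    noise_scale: float = 0.05,
) -> Session:
    """Run + rest session for end-to-end cohort analysis.

    Timeline: a running epoch (theta planted, optionally with a
    theta-coupled epsilon rhythm) followed by a rest epoch with planted
    ripple-like events. Each cell fires theta-locked during running and
    event-locked/gated during rest.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 2026]))
    total = run_duration + rest_duration
    cfg = SimConfig(total, fs, seed, noise_exponent, noise_scale)
    background = generate_background_lfp(cfg)
    run = (0.0, run_duration)
    rest = (run_duration, total)

    rhythms = [PlantedRhythm("theta", theta_freq, theta_amplitude, [run])]
    if epsilon_coupling is not None:
        rhythms.append(
            PlantedRhythm(
                "epsilon", 110.0, theta_amplitude / 4.0, [run], coupling=epsilon_coupling
            )
        )
    with_theta, gt_rhy = plant_rhythms(background, rhythms)

    events, stats = _calibrated_events(background, rest, n_events, snr, rng)
    lfp, gt_ev = plant_events(with_theta, events)
    gt = gt_rhy.merge(gt_ev)
    gt.extra.update(stats)
    mu_d, sd_d = _detection_env_stats(lfp, rest)
    gt.extra.update({"det_env_mean": mu_d, "det_env_sd": sd_d})

    speed = generate_speed_trace([("run", run_duration), ("rest", rest_duration)])
    theta_phase = gt.phases["theta"]
    event_phase = _event_phase_series(events, lfp.n_samples, fs)

    spikes: dict[str, SpikeTrain] = {}
    n = lfp.n_samples
    t_idx_rest = int(run_duration * fs)
    for i, spec in enumerate(cells):
        rate = np.zeros(n)
        run_valid = ~np.isnan(theta_phase)
        rate[run_valid] = spec.rate_run * von_mises_rate_factor(
            theta_phase[run_valid], spec.theta_phase, spec.theta_kappa
        )
        rate[t_idx_rest:] = spec.rate_rest
        ev_valid = ~np.isnan(event_phase)
        rate[ev_valid] = (
            spec.rate_rest
            * spec.event_gain
            * von_mises_rate_factor(event_phase[ev_valid], spec.event_phase, spec.event_kappa)
        )
        sub_seed = np.random.SeedSequence([seed, 11, i])
        cell_rng = np.random.default_rng(sub_seed)
        times = _thin_rate(rate, fs, cell_rng, spec.refractory)
        times = _insert_doublets(times, events, spec.doublet_prob, cell_rng)
        spikes[spec.cell_id] = SpikeTrain(times, spec.cell_id)
        gt.cells[spec.cell_id] = SpikeModel(
            spec.rate_rest,
            spec.event_phase,
            spec.event_kappa,
            spec.event_gain,
            spec.doublet_prob,
            spec.refractory,
        )
    return Session(lfp, speed, spikes, gt, [run], [rest])
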