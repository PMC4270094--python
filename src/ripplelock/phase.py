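"""Oscillation phase assignment and circular statistics.

Phase convention: 0 deg = cycle trough, 180 deg = peak; ascending limb maps
to 0-180 deg, descending limb to 180-360 deg. The default phase extractor
interpolates linearly between detected troughs and peaks, which realizes
this convention exactly even for asymmetric cycles; analytic-signal phase is
available as an alternative.

The per-cell summary statistic is the resultant vector of spike phases:
``r = |sum exp(i*theta_j)| / n`` measures modulation strength (0 = no phase
preference, 1 = all phases identical) and its argument is the preferred
(mean) phase. Uniformity is tested with the Rayleigh test and mean
directions are compared across groups with the Watson-Williams circular
one-way ANOVA.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats as spstats

from .core import LFPRecording, SpikeTrain, in_intervals
from .signal import OscillationBand

__all__ = [
    "PhaseSeries",
    "PhaseLockingResult",
    "instantaneous_phase",
    "spike_phases",
    "resultant",
    "rayleigh_test",
    "watson_williams",
    "phase_histogram",
    "circular_mean_deg",
    "circular_std_deg",
    "kappa_from_r",
]


@dataclass
class PhaseSeries:
    """Per-sample oscillation phase in degrees [0, 360); NaN = unusable."""

    phase: np.ndarray
    fs: float
    band: OscillationBand | None = None
    method: str = "landmark"

    @property
    def times(self) -> np.ndarray:
        return np.arange(self.phase.size) / self.fs


@dataclass
class PhaseLockingResult:
    """Resultant-vector summary of one cell's spike phases."""

    n: int
    mean_phase: float  # deg in [0, 360); NaN when undefined (r == 0)
    r: float
    rayleigh_p: float = float("nan")

    @property
    def mean_phase_defined(self) -> bool:
        return not np.isnan(self.mean_phase)


def instantaneous_phase(
    filtered: LFPRecording,
    landmarks: tuple[np.ndarray, np.ndarray] | None = None,
    method: str = "landmark",
) -> PhaseSeries:
    """Phase series of a band-passed trace under the trough-0 convention.

    ``landmark`` (default): piecewise-linear interpolation assigning 0 deg to
    each trough and 180 deg to each peak; samples before the first or after
    the last landmark are NaN. ``analytic``: Hilbert phase shifted so that
    troughs of a pure tone map to 0 deg.
    """
    if method == "analytic":
        from scipy.signal import hilbert

        ang = np.angle(hilbert(filtered.data))
        return PhaseSeries((np.degrees(ang) + 180.0) % 360.0, filtered.fs, method=method)
    if method != "landmark":
        raise ValueError(f"unknown phase method {method!r}")
    if landmarks is None:
        from .detect import find_cycle_landmarks

        landmarks = find_cycle_landmarks(filtered)
    troughs, peaks = landmarks
    if len(troughs) + len(peaks) < 2:
        raise ValueError("need at least two cycle landmarks")
    pts = np.concatenate([troughs, peaks])
    kinds = np.concatenate([np.zeros(len(troughs)), np.ones(len(peaks))])
    order = np.argsort(pts)
    pts, kinds = pts[order], kinds[order]
    if np.any(kinds[1:] == kinds[:-1]):
        raise ValueError("landmarks must strictly alternate trough/peak")
    # strictly alternating landmarks each advance the unwrapped phase by
    # 180 deg; the first trough anchors 0 deg (a leading peak sits at -180)
    vals = 180.0 * np.arange(pts.size, dtype=float)
    vals += 0.0 if kinds[0] == 0 else -180.0
    t = np.arange(filtered.n_samples) / filtered.fs
    unwrapped = np.interp(t, pts, vals)
    phase = unwrapped % 360.0
    phase[(t < pts[0]) | (t > pts[-1])] = np.nan
    return PhaseSeries(phase, filtered.fs, method="landmark")


def spike_phases(
    spikes: SpikeTrain, phases: PhaseSeries, epochs
) -> tuple[np.ndarray, int]:
    """Phase of each in-epoch spike (nearest-sample lookup).

    Returns (phases in degrees, number of excluded spikes). Spikes outside
    the epochs, outside the trace, or on unusable (NaN) spans are excluded.
    """
    epochs = np.asarray(epochs, dtype=float).reshape(-1, 2)
    if epochs.size == 0:
        raise ValueError("empty epoch set")
    mask = in_intervals(spikes.times, epochs)
    idx = np.round(spikes.times[mask] * phases.fs).astype(int)
    valid = (idx >= 0) & (idx < phases.phase.size)
    vals = phases.phase[idx[valid]]
    ok = ~np.isnan(vals)
    out = vals[ok]
    return out, int(spikes.n_spikes - out.size)


def _to_complex(phases_deg) -> np.ndarray:
    return np.exp(1j * np.deg2rad(np.asarray(phases_deg, dtype=float)))


def circular_mean_deg(phases_deg) -> float:
    """Circular mean direction in [0, 360)."""
    return float(np.degrees(np.angle(np.mean(_to_complex(phases_deg)))) % 360.0)


def circular_std_deg(phases_deg) -> float:
    """Circular standard deviation sqrt(-2 ln r), in degrees."""
    r = np.abs(np.mean(_to_complex(phases_deg)))
    r = min(float(r), 1.0)
    if r == 0:
        return float("inf")
    return float(np.degrees(np.sqrt(-2.0 * np.log(r))))


def resultant(phases_deg) -> PhaseLockingResult:
    """Resultant vector of spike phases: length r and mean direction.

    The mean phase is flagged undefined (NaN) when r is numerically zero,
    e.g. for perfectly symmetric phase sets.
    """
    phases_deg = np.asarray(phases_deg, dtype=float)
    if phases_deg.size == 0:
        raise ValueError("need at least one phase")
    vec = np.mean(_to_complex(phases_deg))
    r = float(np.abs(vec))
    if r < 1e-12:
        mean = float("nan")
        r = 0.0
    else:
        mean = float(np.degrees(np.angle(vec)) % 360.0)
    return PhaseLockingResult(n=int(phases_deg.size), mean_phase=mean, r=min(r, 1.0))


def rayleigh_test(phases_deg) -> float:
    """Rayleigh test of circular uniformity; returns the p-value.

    Uses Z = n r^2 with the standard finite-n correction
    p = exp(sqrt(1 + 4n + 4(n^2 - R^2)) - (1 + 2n)), R = n r,
    which is bounded in (0, 1]. Requires n >= 5 for the approximation.
    """
    phases_deg = np.asarray(phases_deg, dtype=float)
    n = phases_deg.size
    if n < 5:
        raise ValueError("Rayleigh test requires at least 5 phases")
    big_r = n * resultant(phases_deg).r
    p = np.exp(np.sqrt(1.0 + 4.0 * n + 4.0 * (n**2 - big_r**2)) - (1.0 + 2.0 * n))
    return float(min(p, 1.0))


def kappa_from_r(r: float) -> float:
    """Invert r = I1(kappa)/I0(kappa) (Fisher's approximation)."""
    if r < 0.53:
        return 2 * r + r**3 + 5 * r**5 / 6
    if r < 0.85:
        return -0.4 + 1.39 * r + 0.43 / (1 - r)
    return 1.0 / (r**3 - 4 * r**2 + 3 * r)


def watson_williams(*groups) -> tuple[float, float]:
    """Watson-Williams circular one-way ANOVA; returns (F, p).

    Tests equality of mean directions across >= 2 groups, assuming von-Mises
    samples with common, sufficiently large concentration; a warning is
    emitted when the pooled concentration is low (r_w < 0.45) or any group
    is small, where the F approximation degrades.
    """
    if len(groups) == 1 and isinstance(groups[0], (list, tuple)) and not np.isscalar(groups[0][0]):
        groups = tuple(groups[0])
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    groups = [np.asarray(g, dtype=float) for g in groups]
    ns = np.array([g.size for g in groups])
    if np.any(ns < 5):
        warnings.warn("Watson-Williams: group with n < 5; F approximation is rough")
    n_total = int(ns.sum())
    big_rs = np.array([g.size * resultant(g).r for g in groups])
    pooled = np.concatenate(groups)
    big_r = pooled.size * resultant(pooled).r
    rw = big_rs.sum() / n_total
    if rw < 0.45:
        warnings.warn("Watson-Williams: low within-group concentration (r_w < 0.45)")
    kappa = kappa_from_r(rw)
    correction = 1.0 + 3.0 / (8.0 * kappa) if kappa > 0 else 1.0
    k = len(groups)
    denom = n_total - big_rs.sum()
    if denom <= 0:
        return float("inf"), 0.0
    f_stat = correction * ((n_total - k) * (big_rs.sum() - big_r)) / ((k - 1) * denom)
    f_stat = max(float(f_stat), 0.0)
    p = float(spstats.f.sf(f_stat, k - 1, n_total - k))
    return f_stat, p


def phase_histogram(phases_deg, n_bins: int = 20) -> np.ndarray:
    """Firing probability per phase bin; bins cover [0, 360) half-open."""
    phases_deg = np.asarray(phases_deg, dtype=float) % 360.0
    if phases_deg.size == 0:
        raise ValueError("need at least one phase")
    counts, _ = np.histogram(phases_deg, bins=n_bins, range=(0.0, 360.0))
    return counts / phases_deg.size
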