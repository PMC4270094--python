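"""Measure spike-LFP phase locking of a theta-modulated cell.

Plants an 8 Hz theta rhythm, generates a spike train von-Mises locked to
251 deg (the descending phase; 0 deg = trough, 180 deg = peak), then
recovers preferred phase, modulation strength r, and Rayleigh significance
from the trace alone.
"""

import numpy as np

import ripplelock as rl
from ripplelock.synth import PlantedRhythm, SimConfig, SpikeModel, generate_background_lfp, generate_spikes, plant_rhythms

cfg = SimConfig(duration=120.0, fs=1000.0, seed=2, noise_scale=0.02)
lfp, truth = plant_rhythms(
    generate_background_lfp(cfg),
    [PlantedRhythm("theta", 8.0, 0.2, [(0.0, 120.0)])],
)
spikes = generate_spikes(
    truth.phases["theta"], cfg.fs, SpikeModel(base_rate=27.0, preferred_phase=251.0, kappa=1.0),
    seed=2,
)

theta = rl.bandpass(lfp, rl.BANDS["theta"])
phase = rl.instantaneous_phase(theta)  # trough->peak landmark interpolation
spike_ph, n_excluded = rl.spike_phases(spikes, phase, [(1.0, 119.0)])

res = rl.resultant(spike_ph)
p = rl.rayleigh_test(spike_ph)
print(f"n spikes        : {res.n} ({n_excluded} excluded)")
print(f"preferred phase : {res.mean_phase:.1f} deg (planted 251)")
print(f"modulation r    : {res.r:.3f} (planted kappa=1 -> r ~ 0.446)")
print(f"Rayleigh p      : {p:.3g}")
# The preferred phase should land within a few degrees of 251 and the
# Rayleigh test should reject uniformity decisively.
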