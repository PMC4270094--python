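"""Quantify event-gated firing: rate modulation, participation, doublets.

Simulates a rest session with two cells — one strongly event-gated that
fires spike doublets within ripple cycles, one event-indifferent — and runs
the spike-shuffle randomization test plus the per-event statistics.
"""

import ripplelock as rl
from ripplelock.sessions import CellSpec, ripple_session

cells = [
    CellSpec("gated", "H-BC", rate_rest=12.0, event_phase=55.0, event_kappa=4.0,
             event_gain=8.0, doublet_prob=0.8),
    CellSpec("indifferent", "C-AAC", rate_rest=6.0, event_kappa=0.0, event_gain=1.0),
]
session = ripple_session(seed=3, rest_duration=300.0, n_events=30, snr=8.0, cells=cells)
events = rl.detect_events(session.lfp, session.rest_intervals)
ripple_band = rl.bandpass(session.lfp, rl.BANDS["ripple"])

for cid, train in session.spikes.items():
    mod = rl.event_rate_modulation(
        train, events, session.rest_intervals, n_surrogates=1000, seed=3
    )
    part = rl.participation_fraction(train, events)
    early = rl.early_spike_fraction(train, events)
    doublets, intra_rate = rl.detect_doublets(train, events, ripple_band)
    print(f"{cid}:")
    print(f"  rate in/out events : {mod.rate_in:.1f} / {mod.rate_out:.1f} Hz "
          f"(p={mod.p:.3g}, {mod.direction})")
    print(f"  participation      : {100 * part:.0f}% of events")
    print(f"  early-spike frac   : {early:.2f}")
    print(f"  doublet events     : {100 * doublets:.0f}%  intra-event {intra_rate:.0f} Hz")
# The gated cell should show a significant rate increase, near-complete
# participation and a high doublet fraction; the indifferent cell none of it.
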