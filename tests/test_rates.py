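"""Firing rates, randomization tests, participation, doublets, histograms."""

import numpy as np
import pytest

from conftest import tone
from ripplelock.core import OscillationEvent, SpikeTrain
from ripplelock.detect import peri_event_windows
from ripplelock.rates import (
    detect_doublets,
    early_spike_fraction,
    event_rate_modulation,
    firing_rate,
    participation_fraction,
    peri_event_histogram,
)


def _regular_events(n=40, first=5.0, spacing=6.0, duration=0.08):
    return [
        OscillationEvent(s, s + duration, s + duration / 2, 1.0)
        for s in first + spacing * np.arange(n)
    ]


class TestFiringRate:
    def test_count_over_duration(self):
        sp = SpikeTrain(np.linspace(0.0, 3.99, 100))
        assert firing_rate(sp, [(0.0, 4.0)]) == pytest.approx(25.0)

    def test_no_spikes(self):
        assert firing_rate(SpikeTrain(np.array([])), [(0.0, 10.0)]) == 0.0

    def test_poisson_rate_within_ci(self):
        hits = 0
        for seed in range(40):
            rng = np.random.default_rng(seed)
            n = rng.poisson(30 * 60)
            sp = SpikeTrain(np.sort(rng.uniform(0, 60, n)))
            if abs(firing_rate(sp, [(0.0, 60.0)]) - 30.0) <= 3.0:
                hits += 1
        assert hits >= 38  # ~95% of seeds within +-3 Hz

    def test_zero_duration_rejected(self):
        with pytest.raises(ValueError):
            firing_rate(SpikeTrain(np.array([1.0])), [])


class TestEventRateModulation:
    def test_cell_firing_only_inside_events(self):
        events = _regular_events()
        times = np.concatenate([[e.start + 0.01, e.start + 0.04] for e in events])
        res = event_rate_modulation(
            SpikeTrain(np.sort(times)), events, [(0.0, 250.0)], n_surrogates=1000, seed=0
        )
        assert res.direction == "increase"
        assert res.p <= 0.01

    def test_suppressed_cell_detected(self):
        events = _regular_events()
        rng = np.random.default_rng(1)
        sp = np.sort(rng.uniform(0, 250, 4000))
        for ev in events:  # delete every in-event spike (gain 0)
            sp = sp[(sp < ev.start) | (sp > ev.end)]
        res = event_rate_modulation(
            SpikeTrain(sp), events, [(0.0, 250.0)], n_surrogates=1000, seed=1
        )
        assert res.direction == "decrease"
        assert res.p <= 0.01

    def test_event_shuffle_mode(self):
        events = _regular_events()
        times = np.concatenate([[e.start + 0.01, e.start + 0.04] for e in events])
        res = event_rate_modulation(
            SpikeTrain(np.sort(times)), events, [(0.0, 250.0)],
            mode="event_shuffle", n_surrogates=500, seed=2,
        )
        assert res.direction == "increase" and res.p <= 0.01

    def test_null_type_one_error(self):
        events = _regular_events()
        rejections = 0
        n_runs = 100
        for i in range(n_runs):
            rng = np.random.default_rng(100 + i)
            sp = SpikeTrain(np.sort(rng.uniform(0, 250, rng.poisson(25 * 250))))
            res = event_rate_modulation(sp, events, [(0.0, 250.0)], n_surrogates=199, seed=i)
            rejections += res.p < 0.05
        assert 0.01 <= rejections / n_runs <= 0.10

    def test_null_p_values_super_uniform(self):
        from scipy.stats import kstest

        events = _regular_events(n=30)
        ps = []
        for i in range(300):
            rng = np.random.default_rng(7000 + i)
            sp = SpikeTrain(np.sort(rng.uniform(0, 250, rng.poisson(20 * 250))))
            ps.append(
                event_rate_modulation(sp, events, [(0.0, 250.0)], n_surrogates=199, seed=i).p
            )
        ps = np.asarray(ps)
        # super-uniform: empirical CDF never far above the diagonal
        grid = np.linspace(0.01, 1.0, 50)
        excess = np.max([np.mean(ps <= g) - g for g in grid])
        assert excess < 0.08

    def test_too_few_surrogates_rejected(self):
        with pytest.raises(ValueError):
            event_rate_modulation(
                SpikeTrain(np.array([1.0])), _regular_events(), [(0.0, 250.0)], n_surrogates=50
            )

    def test_time_shift_invariance(self):
        events = _regular_events(n=10)
        rng = np.random.default_rng(3)
        sp = SpikeTrain(np.sort(rng.uniform(0, 70, 500)))
        a = event_rate_modulation(sp, events, [(0.0, 70.0)], n_surrogates=200, seed=4)
        shift = 1234.5
        moved = [
            OscillationEvent(e.start + shift, e.end + shift, e.peak_time + shift, 1.0)
            for e in events
        ]
        b = event_rate_modulation(
            sp.shift(shift), moved, [(shift, 70.0 + shift)], n_surrogates=200, seed=4
        )
        assert b.rate_in == pytest.approx(a.rate_in, rel=1e-9)
        assert b.rate_out == pytest.approx(a.rate_out, rel=1e-9)
        assert b.p == a.p


class TestParticipation:
    def test_every_event_hit(self):
        events = _regular_events(n=10)
        sp = SpikeTrain(np.array([e.start + 0.01 for e in events]))
        assert participation_fraction(sp, events) == 1.0

    def test_no_spikes(self):
        assert participation_fraction(SpikeTrain(np.array([])), _regular_events(5)) == 0.0

    def test_matches_generator_per_event_counts(self):
        from ripplelock.synth import PlantedEvent, SpikeModel, generate_spikes

        fs = 1000.0
        planted = [PlantedEvent(1.0 + 2.0 * k, 0.1, 140.0, 1.0) for k in range(30)]
        model = SpikeModel(base_rate=0.0)  # only event-gated firing possible
        # base rate zero means no spikes at all; use tiny base + huge gain
        model = SpikeModel(base_rate=0.15, event_gain=200.0)
        st = generate_spikes(None, fs, model, events=planted, seed=5, n_samples=62_000)
        events = [OscillationEvent(p.start, p.end, p.start + 0.05, 1.0) for p in planted]
        frac = participation_fraction(st, events)
        per_event = [
            np.any((st.times >= p.start) & (st.times <= p.end)) for p in planted
        ]
        assert frac == pytest.approx(np.mean(per_event))

    def test_monotone_in_event_gain(self):
        from ripplelock.synth import PlantedEvent, SpikeModel, generate_spikes

        fs = 1000.0
        planted = [PlantedEvent(1.0 + 2.0 * k, 0.08, 140.0, 1.0) for k in range(40)]
        events = [OscillationEvent(p.start, p.end, p.start + 0.04, 1.0) for p in planted]
        fracs = []
        for gain in (1.0, 5.0, 25.0):
            st = generate_spikes(
                None, fs, SpikeModel(base_rate=2.0, event_gain=gain),
                events=planted, seed=6, n_samples=82_000,
            )
            fracs.append(participation_fraction(st, events))
        assert fracs == sorted(fracs)


class TestEarlySpikeFraction:
    def test_all_before_peak(self):
        events = _regular_events(n=5)
        sp = SpikeTrain(np.array([e.start + 0.01 for e in events]))  # peak at +0.04
        assert early_spike_fraction(sp, events) == 1.0

    def test_all_at_event_end(self):
        events = _regular_events(n=5)
        sp = SpikeTrain(np.array([e.end - 0.001 for e in events]))
        assert early_spike_fraction(sp, events) == 0.0

    def test_symmetric_spiking_near_half(self):
        events = _regular_events(n=50, duration=0.1)
        rng = np.random.default_rng(7)
        times = np.concatenate([rng.uniform(e.start, e.end, 20) for e in events])
        frac = early_spike_fraction(SpikeTrain(np.sort(times)), events)
        assert frac == pytest.approx(0.5, abs=0.05)

    def test_no_in_event_spikes_flagged(self):
        assert np.isnan(early_spike_fraction(SpikeTrain(np.array([0.1])), _regular_events(3)))


class TestDoublets:
    def _ripple_trace(self, duration=10.0, fs=2000.0, freq=140.0):
        return tone(freq, duration=duration, fs=fs)

    def test_two_spikes_in_one_cycle_counts(self):
        tr = self._ripple_trace()
        events = [OscillationEvent(1.0, 1.1, 1.05, 1.0)]
        # 3 ms apart inside one 140 Hz cycle (cycle = troughs 1.0143-1.0214)
        sp = SpikeTrain(np.array([1.0155, 1.0185]))
        frac, _ = detect_doublets(sp, events, tr)
        assert frac == 1.0

    def test_one_spike_per_cycle_no_doublets(self):
        tr = self._ripple_trace()
        events = [OscillationEvent(1.0, 1.1, 1.05, 1.0)]
        period = 1 / 140.0
        sp = SpikeTrain(1.002 + period * np.arange(12))
        frac, rate = detect_doublets(sp, events, tr)
        assert frac == 0.0
        assert rate == pytest.approx(12 / 0.1, rel=0.1)

    def test_generator_doublet_probability_recovered(self):
        from ripplelock.synth import PlantedEvent, SpikeModel, generate_spikes

        fs = 2000.0
        planted = [PlantedEvent(0.5 + 0.5 * k, 0.1, 140.0, 1.0) for k in range(60)]
        tr = self._ripple_trace(duration=31.0, fs=fs)
        events = [OscillationEvent(p.start, p.end, p.start + 0.05, 1.0) for p in planted]
        fracs = {}
        for prob in (0.1, 0.8):
            model = SpikeModel(base_rate=1.0, event_gain=60.0, doublet_prob=prob)
            st = generate_spikes(None, fs, model, events=planted, seed=8, n_samples=62_000)
            fracs[prob], _ = detect_doublets(st, events, tr)
        assert fracs[0.8] > fracs[0.1]
        assert fracs[0.8] == pytest.approx(
            1 - (1 - 0.8) ** 1, abs=0.25
        )  # most events contain a spiking cycle


class TestPeriEventHistogram:
    def test_bin_layout_and_empty(self):
        windows = peri_event_windows(_regular_events(n=3))
        h = peri_event_histogram(SpikeTrain(np.array([])), windows)
        assert h.probs.shape == (100,)
        assert not h.probs.any()

    def test_flat_for_uniform_cell(self):
        events = _regular_events(n=60, spacing=4.0, duration=0.5)
        windows = peri_event_windows(events)
        rng = np.random.default_rng(9)
        sp = SpikeTrain(np.sort(rng.uniform(0, 250, 10_000)))
        h = peri_event_histogram(sp, windows)
        # uniform firing: smoothed profile flat (max/min ratio below 1.5)
        coarse = h.probs.reshape(20, 5).mean(axis=1)
        assert coarse.max() / coarse.min() < 1.5

    def test_gated_cell_elevated_during(self):
        events = _regular_events(n=50)
        windows = peri_event_windows(events)
        rng = np.random.default_rng(10)
        out_sp = rng.uniform(0, 250, 1000)
        in_sp = np.concatenate([rng.uniform(e.start, e.end, 5) for e in events])
        h = peri_event_histogram(SpikeTrain(np.sort(np.r_[out_sp, in_sp])), windows)
        assert h.probs[40:60].mean() > 3 * h.probs[:40].mean()

    def test_during_bins_sum_to_mean_in_event_count(self):
        events = _regular_events(n=25)
        windows = peri_event_windows(events)
        rng = np.random.default_rng(11)
        sp = SpikeTrain(np.sort(rng.uniform(0, 160, 4000)))
        h = peri_event_histogram(sp, windows)
        counts = [
            np.count_nonzero((sp.times >= e.start) & (sp.times < e.end)) for e in events
        ]
        assert h.probs[40:60].sum() == pytest.approx(np.mean(counts), abs=1e-9)
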