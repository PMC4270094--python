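"""Phase assignment and circular statistics."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import i0 as bessel_i0, i1 as bessel_i1
from scipy.stats import vonmises

from conftest import tone
from ripplelock.core import LFPRecording, SpikeTrain
from ripplelock.detect import find_cycle_landmarks
from ripplelock.phase import (
    circular_mean_deg,
    instantaneous_phase,
    phase_histogram,
    rayleigh_test,
    resultant,
    spike_phases,
    watson_williams,
)


class TestInstantaneousPhase:
    def test_trough_and_peak_convention(self):
        tr = tone(8.0, duration=1.0)
        ps = instantaneous_phase(tr)
        assert ps.phase[0] == pytest.approx(0.0)  # t=0 is a trough of -cos
        i_peak = int(round((1 / 16) * 1000))
        assert ps.phase[i_peak] == pytest.approx(180.0, abs=3.0)

    def test_midpoint_interpolates_to_90(self):
        tr = tone(8.0, duration=1.0)
        ps = instantaneous_phase(tr)
        i_mid = int(round((1 / 32) * 1000))  # halfway up the ascending limb
        assert ps.phase[i_mid] == pytest.approx(90.0, abs=6.0)

    def test_asymmetric_cycle_still_maps_limbs(self):
        # sawtooth-like cycle: slow rise (3/4 period), fast fall; landmark
        # interpolation must still pin trough->peak onto [0, 180]
        fs = 1000.0
        period = 0.25
        t = np.arange(0, 2.0, 1 / fs)
        frac = (t % period) / period
        x = np.where(frac < 0.75, -1 + 2 * frac / 0.75, 1 - 2 * (frac - 0.75) / 0.25)
        ps = instantaneous_phase(LFPRecording(x, fs))
        # halfway up the slow ascending limb -> 90 deg
        i = int(round((period * 0.375 + period) * fs))
        assert ps.phase[i] == pytest.approx(90.0, abs=5.0)
        # halfway down the fast descending limb -> 270 deg
        i = int(round((period * (0.75 + 0.125) + period) * fs))
        assert ps.phase[i] == pytest.approx(270.0, abs=10.0)

    def test_analytic_method_matches_on_tone(self):
        tr = tone(8.0, duration=2.0)
        a = instantaneous_phase(tr, method="analytic")
        b = instantaneous_phase(tr, method="landmark")
        sel = slice(300, 1700)
        diff = np.abs((a.phase[sel] - b.phase[sel] + 180) % 360 - 180)
        assert np.nanmax(diff) < 5.0

    def test_too_few_landmarks_rejected(self):
        flat = LFPRecording(np.linspace(0, 1, 100), 1000.0)
        with pytest.raises(ValueError):
            instantaneous_phase(flat, landmarks=(np.array([]), np.array([0.05])))


class TestSpikePhases:
    def test_spike_at_trough_reads_zero(self):
        tr = tone(8.0, duration=1.0)
        ps = instantaneous_phase(tr)
        troughs, _ = find_cycle_landmarks(tr)
        ph, excl = spike_phases(SpikeTrain(troughs[1:3]), ps, [(0.0, 1.0)])
        np.testing.assert_allclose(ph, 0.0, atol=1.0)
        assert excl == 0

    def test_out_of_epoch_spikes_excluded(self):
        tr = tone(8.0, duration=1.0)
        ps = instantaneous_phase(tr)
        ph, excl = spike_phases(SpikeTrain(np.array([0.2, 0.4])), ps, [(0.5, 0.9)])
        assert ph.size == 0 and excl == 2

    def test_planted_sharp_locking_recovered(self):
        from ripplelock.synth import SpikeModel, generate_spikes

        fs = 10_000.0
        tr = tone(8.0, duration=20.0, fs=fs)
        ps = instantaneous_phase(tr)
        phase = (360.0 * 8.0 * np.arange(tr.n_samples) / fs) % 360.0
        st_ = generate_spikes(phase, fs, SpikeModel(20.0, 126.0, 1e6), seed=6)
        ph, _ = spike_phases(st_, ps, [(0.5, 19.5)])
        diff = np.abs((ph - 126.0 + 180) % 360 - 180)
        assert np.max(diff) < 2.0

    def test_empty_epochs_rejected(self):
        tr = tone(8.0, duration=1.0)
        ps = instantaneous_phase(tr)
        with pytest.raises(ValueError):
            spike_phases(SpikeTrain(np.array([0.5])), ps, [])


class TestResultant:
    def test_identical_angles(self):
        res = resultant([90.0, 90.0, 90.0])
        assert res.r == pytest.approx(1.0)
        assert res.mean_phase == pytest.approx(90.0)

    def test_symmetric_angles_undefined_mean(self):
        res = resultant([0.0, 90.0, 180.0, 270.0])
        assert res.r == 0.0
        assert np.isnan(res.mean_phase)

    def test_hand_computed_example(self):
        res = resultant([0.0, 0.0, 90.0])
        assert res.r == pytest.approx(np.sqrt(5) / 3, abs=1e-12)
        assert res.mean_phase == pytest.approx(np.degrees(np.arctan2(1, 2)), abs=1e-9)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            resultant([])


class TestRayleigh:
    def test_concentrated_sample_tiny_p(self):
        assert rayleigh_test([33.0] * 100) < 1e-10

    def test_uniform_sample_calibration(self):
        rng = np.random.default_rng(12)
        n_ok = 0
        for _ in range(100):
            p = rayleigh_test(rng.uniform(0, 360, 10_000))
            n_ok += p > 0.01
        assert n_ok >= 95

    def test_against_permutation_null(self):
        # null distribution of r for n=20 uniform phases, 100k draws
        rng = np.random.default_rng(13)
        theta = rng.uniform(0, 2 * np.pi, size=(100_000, 20))
        r_null = np.abs(np.exp(1j * theta).mean(axis=1))
        target_r = 0.3
        p_mc = np.mean(r_null >= target_r)
        # build a 20-sample set with r == 0.3 exactly: two clusters
        # r = |a*e^{i0} + (20-a)*e^{i pi}|/20 -> use 13 at 0deg, 7 at 180deg
        sample = [0.0] * 13 + [180.0] * 7  # r = 6/20 = 0.3
        p_mine = rayleigh_test(sample)
        assert p_mine == pytest.approx(p_mc, rel=0.10)

    def test_small_n_rejected(self):
        with pytest.raises(ValueError):
            rayleigh_test([0.0, 10.0, 20.0])

    def test_matches_independent_implementation(self):
        pingouin = pytest.importorskip("pingouin")
        rng = np.random.default_rng(14)
        ph = np.degrees(rng.vonmises(1.0, 0.7, 80)) % 360
        _, p_ref = pingouin.circ_rayleigh(np.deg2rad(ph))
        assert rayleigh_test(ph) == pytest.approx(p_ref, rel=1e-9)


class TestWatsonWilliams:
    def test_identical_groups_no_difference(self):
        g = [10.0, 25.0, 40.0, 15.0, 30.0]
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            f, p = watson_williams(g, list(g))
        assert f == pytest.approx(0.0, abs=1e-9)
        assert p == pytest.approx(1.0)

    def test_separated_groups_detected(self):
        rng = np.random.default_rng(15)
        g1 = np.degrees(rng.vonmises(np.deg2rad(55), 10, 50)) % 360
        g2 = np.degrees(rng.vonmises(np.deg2rad(126), 10, 50)) % 360
        _, p = watson_williams(g1, g2)
        assert p < 0.001

    def test_type_one_error_near_alpha(self):
        # three groups, one shared mean direction, kappa = 5
        rng = np.random.default_rng(16)
        rejections = 0
        n_runs = 500
        for _ in range(n_runs):
            gs = [np.degrees(rng.vonmises(1.0, 5.0, 30)) % 360 for _ in range(3)]
            _, p = watson_williams(*gs)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_runs <= 0.09

    def test_single_group_rejected(self):
        with pytest.raises(ValueError):
            watson_williams([1.0, 2.0, 3.0, 4.0, 5.0])

    def test_low_concentration_warns(self):
        rng = np.random.default_rng(17)
        g1 = rng.uniform(0, 360, 30)
        g2 = rng.uniform(0, 360, 30)
        with pytest.warns(UserWarning, match="concentration"):
            watson_williams(g1, g2)


class TestPhaseHistogram:
    def test_uniform_sample(self):
        ph = np.repeat(np.arange(0, 360, 18.0), 18)  # 20 values per bin
        probs = phase_histogram(ph, n_bins=20)
        np.testing.assert_allclose(probs, 0.05)

    def test_point_mass(self):
        probs = phase_histogram([0.0] * 7, n_bins=20)
        assert probs[0] == 1.0 and probs[1:].sum() == 0.0

    def test_von_mises_bin_masses(self):
        # analytic bin-integral oracle at kappa = 4
        rng = np.random.default_rng(18)
        ph = np.degrees(rng.vonmises(np.deg2rad(180.0), 4.0, 10_000)) % 360
        probs = phase_histogram(ph, n_bins=20)
        edges = np.deg2rad(np.linspace(0, 360, 21) - 180.0)
        cdf = vonmises.cdf(edges, 4.0)
        expected = np.diff(cdf)
        assert np.abs(probs - expected).max() < 0.02


class TestInvariants:
    @given(delta=st.floats(-360.0, 720.0))
    @settings(max_examples=30, deadline=None, derandomize=True)
    def test_rotation_equivariance(self, delta):
        rng = np.random.default_rng(19)
        ph = np.degrees(rng.vonmises(0.7, 2.0, 60)) % 360
        base = resultant(ph)
        rot = resultant((ph + delta) % 360)
        assert rot.r == pytest.approx(base.r, abs=1e-9)
        assert abs((rot.mean_phase - base.mean_phase - delta + 180) % 360 - 180) < 1e-6
        assert rayleigh_test((ph + delta) % 360) == pytest.approx(rayleigh_test(ph), rel=1e-9)

    def test_recovery_of_planted_kappa_and_phase(self):
        rng = np.random.default_rng(20)
        kappa, mu = 2.0, 237.0
        ph = np.degrees(rng.vonmises(np.deg2rad(mu), kappa, 2000)) % 360
        res = resultant(ph)
        assert abs((res.mean_phase - mu + 180) % 360 - 180) < 5.0
        assert res.r == pytest.approx(bessel_i1(kappa) / bessel_i0(kappa), abs=0.03)

    def test_histogram_resultant_consistency(self):
        rng = np.random.default_rng(21)
        ph = np.degrees(rng.vonmises(1.0, 3.0, 5000)) % 360
        n_bins = 72
        probs = phase_histogram(ph, n_bins=n_bins)
        centers = np.deg2rad(np.arange(n_bins) * 360.0 / n_bins + 180.0 / n_bins)
        r_binned = np.abs(np.sum(probs * np.exp(1j * centers)))
        assert r_binned == pytest.approx(resultant(ph).r, abs=2e-3)
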