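"""Navigator-to-motion-signal processing chain."""

import numpy as np
import pytest

import xdflow as x
from xdflow.physio import (center_motion, coil_cluster, detect_resp_triggers,
                           estimate_resp_rate, highpass_drift, lowpass_cardiac,
                           navigator_displacement, normalize_motion,
                           resp_bandlimit, resp_phase)


def _nav_line(n=64, delta_px=0.0, rng=None, snr=None):
    """Reference/shifted navigator pair along one axis."""
    k = np.arange(n) - n // 2
    profile = np.exp(-((k / (n / 6)) ** 2)) + 0.1          # smooth magnitude
    ref = profile.astype(complex)
    # forward-FFT convention: a +D image shift gives phase -2 pi k D / N
    nav = ref * np.exp(-1j * 2 * np.pi * k * delta_px / n)
    if snr is not None:
        scale = np.abs(ref).max() / snr
        nav = nav + scale * (rng.standard_normal(n) + 1j * rng.standard_normal(n))
    return nav, ref


class TestNavigatorDisplacement:
    def test_identical_readouts_give_zero(self):
        nav, ref = _nav_line()
        d = navigator_displacement(nav[None, None], ref[None, None], (64,))
        assert d[0, 0] == pytest.approx(0.0, abs=1e-12)

    def test_known_shift_recovered(self):
        nav, ref = _nav_line(delta_px=1.5)
        d = navigator_displacement(nav[None, None], ref[None, None], (64,))
        assert d[0, 0] == pytest.approx(1.5, abs=1e-9)

    def test_noisy_shift_within_tenth_pixel(self, rng):
        errs = []
        for _ in range(50):
            nav, ref = _nav_line(delta_px=1.5, rng=rng, snr=20)
            d = navigator_displacement(nav[None, None], ref[None, None], (64,))
            errs.append(abs(d[0, 0] - 1.5))
        assert np.median(errs) < 0.1

    def test_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            navigator_displacement(np.ones((1, 1, 8), complex),
                                   np.zeros((1, 1, 8), complex), (8,))


class TestFilters:
    fs = 250.0

    def test_lowpass_keeps_constant(self):
        s = np.full(2000, 3.3)
        np.testing.assert_allclose(lowpass_cardiac(s, self.fs, 90.0), s,
                                   atol=1e-9)

    def test_lowpass_attenuates_heart_rate(self):
        t = np.arange(5000) / self.fs
        hr = 120.0
        s = np.sin(2 * np.pi * (hr / 60.0) * t)
        out = lowpass_cardiac(s, self.fs, hr)
        assert np.abs(out[1000:-1000]).max() < 0.2

    def test_lowpass_preserves_respiratory_band(self):
        t = np.arange(5000) / self.fs
        s = np.sin(2 * np.pi * 0.3 * t)
        out = lowpass_cardiac(s, self.fs, 120.0)
        assert np.abs(out[1000:-1000]).max() == pytest.approx(1.0, rel=0.05)

    def test_highpass_removes_dc(self):
        s = np.full(4000, 7.0)
        assert np.abs(highpass_drift(s, self.fs)).max() < 1e-6

    def test_highpass_preserves_1hz(self):
        # interior window excludes the long zero-phase transient of the
        # 0.1 Hz filter (~tens of seconds)
        t = np.arange(int(120 * self.fs)) / self.fs
        out = highpass_drift(np.sin(2 * np.pi * t), self.fs)
        m = int(30 * self.fs)
        assert np.abs(out[m:-m]).max() == pytest.approx(1.0, rel=0.05)

    def test_highpass_suppresses_slow_ramp(self):
        n = int(300 * self.fs)                    # 5-minute linear drift
        ramp = np.linspace(0, 10, n)
        out = highpass_drift(ramp, self.fs)
        interior = out[int(10 * self.fs):-int(10 * self.fs)]
        assert np.abs(interior).max() < 0.1 * 10

    def test_resp_bandlimit_attenuates_resp_rate(self):
        t = np.arange(8000) / self.fs
        rr = 15.0
        out = resp_bandlimit(np.sin(2 * np.pi * rr / 60 * t), self.fs, rr)
        assert np.abs(out[2000:-2000]).max() < 0.9


class TestCoilCluster:
    def test_identical_coils_pass_through(self, rng):
        s = rng.standard_normal(500)
        out = coil_cluster(np.tile(s, (6, 1)))
        np.testing.assert_allclose(out, s)

    def test_sign_flipped_coils_align(self, rng):
        s = rng.standard_normal(500)
        sigs = np.stack([s, -s, s, -s])
        out = coil_cluster(sigs)
        assert np.corrcoef(out, s)[0, 1] > 0.999

    def test_noise_coil_excluded(self, rng):
        s = np.sin(np.linspace(0, 20 * np.pi, 800))
        sigs = np.tile(s, (8, 1)).copy()
        sigs[3] = rng.standard_normal(800)        # one pure-noise coil
        out = coil_cluster(sigs)
        assert abs(np.corrcoef(out, s)[0, 1]) > 0.99

    def test_no_cluster_falls_back_with_warning(self, rng):
        sigs = rng.standard_normal((4, 300))
        with pytest.warns(UserWarning):
            coil_cluster(sigs, threshold=0.999)


class TestNormalizeCenter:
    def test_constant_motion_flags_motion_free(self):
        d1, free = normalize_motion(np.tile([2.0, 0.0, 0.0], (10, 1)))
        assert free and np.all(d1 == 0)

    def test_two_point_distribution_matches_population_std(self):
        d0 = np.zeros((10, 3))
        d0[5:, 0] = 2.0                            # norms {0, 2}, std = 1
        d1, free = normalize_motion(d0)
        assert not free
        np.testing.assert_allclose(np.unique(d1), [0.0, 2.0])

    def test_scale_invariance(self, rng):
        d0 = rng.standard_normal((200, 3))
        d1a, _ = normalize_motion(d0)
        d1b, _ = normalize_motion(5.0 * d0)
        np.testing.assert_allclose(d1a, d1b)

    def test_center_on_point_mass(self, rng):
        d1 = 1.3 + 0.001 * rng.standard_normal(1000)
        d, d_ref = center_motion(d1)
        assert d_ref == pytest.approx(1.3, abs=0.01)
        assert np.abs(d).max() < 0.02

    def test_center_picks_dominant_mode(self, rng):
        d1 = np.concatenate([
            0.5 + 0.01 * rng.standard_normal(800),
            2.0 + 0.01 * rng.standard_normal(200)])
        _, d_ref = center_motion(d1)
        assert d_ref == pytest.approx(0.5, abs=0.05)

    def test_centering_idempotent(self, rng):
        d1 = rng.normal(1.0, 0.3, 2000)
        d, _ = center_motion(d1)
        _, ref2 = center_motion(d)
        assert abs(ref2) < 0.1


class TestRespiratoryTriggers:
    def test_sinusoid_triggers_one_period_apart(self):
        fs, period = 100.0, 4.0
        t = np.arange(int(60 * fs)) / fs
        d = np.sin(2 * np.pi * t / period)
        trig = detect_resp_triggers(d, fs)
        spacing = np.diff(trig) / fs
        np.testing.assert_allclose(spacing, period, atol=1.0 / fs + 1e-9)

    def test_phase_zero_at_trigger_and_half_midway(self):
        trig = np.array([100, 200, 300])
        r = resp_phase(400, trig)
        assert r[100] == 0.0 and r[200] == 0.0
        assert r[150] == pytest.approx(0.5)

    def test_rate_estimate_on_asymmetric_rectified_signal(self):
        # a rectified asymmetric breath signal must not double the rate
        fs, rate = 100.0, 15.0
        t = np.arange(int(120 * fs)) / fs
        s = (0.5 * (1 - np.cos(2 * np.pi * rate / 60 * t))) ** 2
        d = np.abs(s - s.mean())
        assert estimate_resp_rate(d, fs) == pytest.approx(rate, rel=0.05)


class TestEndToEnd:
    def test_recovered_respiratory_period_and_trigger_count(self):
        cfg = x.PhantomConfig(
            grid_size=32, n_coils=6, scan_duration_s=40.0, TR_ms=4.0,
            resp_amplitude_mm=6.0, resp_rate=15.0, seed=5)
        ph = x.Phantom(cfg)
        order = x.build_view_order((32, 32), 4, 4, spokes_per_mask=20,
                                   density_exponent=0.3)
        table = x.simulate_acquisition(ph, order)
        sig = x.extract_physio(table)
        assert sig.resp_rate == pytest.approx(cfg.resp_rate, rel=0.02)
        breaths = cfg.scan_duration_s * cfg.resp_rate / 60.0
        assert abs(len(sig.resp_triggers) - breaths) <= 1

    def test_pipeline_deterministic(self, small_acquisition):
        a = x.extract_physio(small_acquisition)
        b = x.extract_physio(small_acquisition)
        np.testing.assert_array_equal(a.d, b.d)
        np.testing.assert_array_equal(a.r, b.r)
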