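import numpy as np
import pytest

from mtmskit import mri_qa as qa
from mtmskit.synth import gen_fid, gen_fid_series, gen_phantom_stacks


def make_fid(scale=1.0, n=256, dwell=4e-6, f0=500.0):
    t = np.arange(n) * dwell
    return qa.FidSignal(scale * np.exp(2j * np.pi * f0 * t - t / 2e-3), dwell)


class TestCorruption:
    def test_identical_fids_ratio_one(self):
        f = make_fid()
        assert qa.corruption_ratio(f, f) == pytest.approx(1.0, rel=1e-12)
        assert not qa.is_corrupted(f, f)

    def test_amplitude_scaling_is_parseval_power(self):
        ref = make_fid()
        assert qa.corruption_ratio(make_fid(0.9), ref) == pytest.approx(0.81, rel=1e-12)
        assert qa.is_corrupted(make_fid(0.9), ref)

    def test_threshold_is_95_percent(self):
        ref = make_fid()
        just_above = make_fid(np.sqrt(0.951))
        just_below = make_fid(np.sqrt(0.949))
        assert not qa.is_corrupted(just_above, ref)
        assert qa.is_corrupted(just_below, ref)

    def test_frequency_domain_ratio_equals_time_domain_power(self):
        # Parseval: integral of |FFT|^2 equals N * time-domain energy
        rng = np.random.default_rng(0)
        x = rng.normal(size=128) + 1j * rng.normal(size=128)
        y = rng.normal(size=128) + 1j * rng.normal(size=128)
        fx = qa.FidSignal(x, 1e-5)
        fy = qa.FidSignal(y, 1e-5)
        ratio_time = np.sum(np.abs(x) ** 2) / np.sum(np.abs(y) ** 2)
        assert qa.corruption_ratio(fx, fy) == pytest.approx(ratio_time, rel=1e-10)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            qa.corruption_ratio(make_fid(n=128), make_fid(n=256))


class TestMinDelay:
    def _series(self, corrupted_mask, step=0.5):
        ref = make_fid()
        out = []
        for i, bad in enumerate(corrupted_mask):
            out.append((i * step, make_fid(0.9 if bad else 1.0)))
        return out, ref

    def test_corrupted_through_4p5_ms_returns_5(self):
        flags = [d <= 4.5 for d in np.arange(0, 10.5, 0.5)]
        series, ref = self._series(flags)
        assert qa.min_artifact_free_delay(series, ref) == pytest.approx(5.0)

    def test_clean_everywhere_returns_zero(self):
        series, ref = self._series([False] * 21)
        assert qa.min_artifact_free_delay(series, ref) == 0.0

    def test_non_monotone_uses_last_corrupted(self, caplog):
        # clean at 2 ms but corrupted again at 3 ms -> 3.5 ms
        flags = [d <= 1.5 or d == 3.0 for d in np.arange(0, 10.5, 0.5)]
        series, ref = self._series(flags)
        with caplog.at_level("WARNING"):
            assert qa.min_artifact_free_delay(series, ref) == pytest.approx(3.5)
        assert any("non-monotone" in r.message for r in caplog.records)

    def test_all_corrupted_returns_sentinel(self):
        series, ref = self._series([True] * 21)
        assert np.isnan(qa.min_artifact_free_delay(series, ref))

    def test_unsorted_delays_rejected(self):
        series, ref = self._series([False] * 3)
        with pytest.raises(ValueError):
            qa.min_artifact_free_delay(series[::-1], ref)


class TestB0Map:
    def test_constant_phase_gives_zero_shift(self):
        tes = np.array(qa.DEFAULT_B0_TES_MS) * 1e-3
        ph = np.ones((len(tes), 8, 8)) * 0.3
        m = qa.b0_map(ph, tes)
        np.testing.assert_allclose(m.shift_hz, 0.0, atol=1e-9)
        assert qa.b0_homogeneity(m, np.ones((8, 8), bool)) == pytest.approx(0.0, abs=1e-9)

    def test_known_100hz_shift_recovered(self):
        tes = np.array(qa.DEFAULT_B0_TES_MS) * 1e-3
        ph = 2 * np.pi * 100.0 * tes[:, None, None] * np.ones((1, 4, 4))
        m = qa.b0_map(ph, tes)
        np.testing.assert_allclose(m.shift_hz, 100.0, atol=1e-9)

    def test_wrapped_linear_gradient_inverted(self):
        tes = np.array(qa.DEFAULT_B0_TES_MS) * 1e-3
        shift = np.linspace(0, 500, 16)[:, None] * np.ones((1, 8))
        ph, _ = gen_phantom_stacks(shift, np.ones_like(shift), noise_sd=0.0)
        m = qa.b0_map(ph, tes)
        np.testing.assert_allclose(m.shift_hz, shift, atol=1.0)

    def test_homogeneity_in_ellipsoid_roi(self):
        tes = np.array(qa.DEFAULT_B0_TES_MS) * 1e-3
        rng = np.random.default_rng(0)
        shift = rng.normal(0.0, 5.0, size=(16, 16))
        ph = 2 * np.pi * shift[None] * tes[:, None, None]
        m = qa.b0_map(ph, tes)
        roi = qa.ellipsoid_roi((16, 16), (8, 8), (5, 7))
        assert qa.b0_homogeneity(m, roi) == pytest.approx(np.std(shift[roi]), rel=1e-6)

    def test_single_echo_rejected(self):
        with pytest.raises(ValueError):
            qa.b0_map(np.zeros((1, 4, 4)), np.array([1.6e-3]))


class TestB1Map:
    def test_unit_ratio_for_pure_sine(self):
        ang = np.array(qa.DEFAULT_B1_ANGLES_DEG, float)
        mags = np.abs(np.sin(np.radians(ang)))[:, None, None] * np.ones((1, 3, 3))
        m = qa.b1_map(mags, ang)
        np.testing.assert_allclose(m.ratio[m.mask], 1.0, atol=1e-6)

    def test_ratio_08_recovered_exactly(self):
        ang = np.array(qa.DEFAULT_B1_ANGLES_DEG, float)
        mags = np.abs(np.sin(0.8 * np.radians(ang)))[:, None, None] * np.ones((1, 2, 2))
        m = qa.b1_map(mags, ang)
        np.testing.assert_allclose(m.ratio[m.mask], 0.8, atol=1e-6)

    def test_one_percent_noise_two_percent_recovery(self):
        shift = np.zeros((4, 4))
        ratio = np.full((4, 4), 0.8)
        _, mags = gen_phantom_stacks(shift, ratio, noise_sd=0.01, seed=1)
        m = qa.b1_map(mags, np.array(qa.DEFAULT_B1_ANGLES_DEG, float))
        assert np.all(np.abs(m.ratio[m.mask] - 0.8) / 0.8 < 0.02)

    def test_flat_voxels_masked_out(self):
        ang = np.array(qa.DEFAULT_B1_ANGLES_DEG, float)
        mags = np.zeros((len(ang), 2, 2))
        mags[:, 0, 0] = np.abs(np.sin(np.radians(ang)))
        m = qa.b1_map(mags, ang)
        assert m.mask[0, 0] and not m.mask[1, 1]


class TestEddy:
    def test_identical_fids_give_unit_curves(self):
        f = make_fid()
        series = {"x": [(d, f) for d in qa.DEFAULT_EDDY_DELAYS_MS]}
        curves = qa.eddy_current_curves(series)
        np.testing.assert_allclose(curves["x"]["power"], 1.0, rtol=1e-12)
        np.testing.assert_allclose(curves["x"]["phase"], 1.0, rtol=1e-12)

    def test_synthetic_eddy_decay_recovers_plateau(self):
        series, _ = gen_fid_series(
            "eddy", seed=2, delays_ms=qa.DEFAULT_EDDY_DELAYS_MS, noise_sd=0.0
        )
        curves = qa.eddy_current_curves({"z": series})
        d = curves["z"]["delay_ms"]
        p = curves["z"]["power"]
        assert abs(p[d == 2000.0][0] - 1.0) < 1e-12
        # tau = 0.3 ms: strongly attenuated at 0 delay, recovered by ~1.5 ms
        assert p[d == 0.0][0] < 0.6
        assert np.all(np.abs(p[d >= 1.5] - 1.0) < 0.02)

    def test_missing_reference_delay_rejected(self):
        f = make_fid()
        with pytest.raises(ValueError):
            qa.eddy_current_curves({"x": [(0.0, f), (1.0, f)]})


class TestInterleaving:
    def test_paper_protocol_slice_interval(self):
        p = qa.plan_interleaving(2000.0, 15, 40.0, 40.0)
        assert p.slice_interval_ms == pytest.approx(2000.0 / 15)
        assert p.slice_interval_ms == pytest.approx(133.333333333, rel=1e-9)

    def test_window_arithmetic_with_and_without_delay(self):
        p40 = qa.plan_interleaving(2000.0, 15, 40.0, 40.0)
        p0 = qa.plan_interleaving(2000.0, 15, 0.0, 40.0)
        assert p40.window_length_ms == pytest.approx(2000.0 / 15 - 80.0)  # ~53 ms
        assert p0.window_length_ms == pytest.approx(2000.0 / 15 - 40.0)  # ~93 ms

    def test_single_slice(self):
        p = qa.plan_interleaving(1000.0, 1, 40.0, 40.0)
        assert len(p.windows_ms) == 1
        assert p.window_length_ms == pytest.approx(1000.0 - 40.0 - 40.0)

    def test_negative_window_is_infeasible(self):
        with pytest.raises(qa.InfeasibleScheduleError):
            qa.plan_interleaving(2000.0, 15, 100.0, 40.0)

    def test_overlong_acquisition_rejected(self):
        with pytest.raises(ValueError):
            qa.plan_interleaving(500.0, 15, 0.0, 40.0)
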