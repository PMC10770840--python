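"""Preprocessing chain: normalization, resampling, filters, windowing."""

import numpy as np
import pytest
from scipy.signal import correlate, correlation_lags

import rppgeval as rp

from .oracles import dominant_frequency, roi_mean_bruteforce


class TestRoiMeanTrace:
    def test_uniform_frames(self):
        frames = np.full((5, 4, 4, 3), 7.0)
        mask = np.ones((4, 4), dtype=bool)
        trace = rp.roi_mean_trace(frames, mask, fps=30)
        for ch in ("red", "green", "blue"):
            assert np.allclose(trace.channel(ch), 7.0)

    def test_half_and_half(self):
        frames = np.zeros((2, 2, 2, 3))
        frames[:, 0, :, :] = 1.0
        trace = rp.roi_mean_trace(frames, np.ones((2, 2), bool), fps=30)
        assert np.allclose(trace.green, 0.5)

    def test_matches_bruteforce_loop(self, rng):
        frames = rng.uniform(0, 255, size=(10, 6, 7, 3))
        mask = rng.uniform(size=(6, 7)) > 0.5
        mask[0, 0] = True  # ensure non-empty
        trace = rp.roi_mean_trace(frames, mask, fps=25)
        expected = roi_mean_bruteforce(frames, mask)
        assert np.allclose(trace.red, expected[:, 0])
        assert np.allclose(trace.green, expected[:, 1])
        assert np.allclose(trace.blue, expected[:, 2])

    def test_region_union_pooling(self):
        # two disjoint regions pool into a single mean
        frames = np.zeros((1, 4, 4, 3))
        frames[0, 0, 0, :] = 4.0
        regions = {"a": np.zeros((4, 4), bool), "b": np.zeros((4, 4), bool)}
        regions["a"][0, 0] = True
        regions["b"][3, 3] = True
        mask = rp.ROIMask(regions=regions)
        trace = rp.roi_mean_trace(frames, mask, fps=30)
        assert trace.red[0] == pytest.approx(2.0)

    def test_errors(self):
        frames = np.zeros((2, 4, 4, 3))
        with pytest.raises(rp.DataError):
            rp.roi_mean_trace(frames, np.zeros((4, 4), bool), fps=30)
        with pytest.raises(rp.DataError):
            rp.roi_mean_trace(frames, np.ones((5, 5), bool), fps=30)

    def test_shipped_landmark_constants(self):
        from rppgeval.roi import ROI_LANDMARKS

        assert ROI_LANDMARKS["forehead"] == (107, 66, 69, 109, 10, 338, 299,
                                             296, 336, 9)
        assert ROI_LANDMARKS["left_cheek"] == (118, 119, 100, 126, 209, 49,
                                               129, 203, 205, 50)
        assert ROI_LANDMARKS["right_cheek"] == (347, 348, 329, 355, 429, 279,
                                                358, 423, 425, 280)


class TestRobustNormalize:
    def test_median_zero_iqr_one(self):
        out = rp.robust_normalize(np.array([1.0, 2, 3, 4, 5]))
        assert np.median(out) == pytest.approx(0.0, abs=1e-12)
        q75, q25 = np.percentile(out, [75, 25])
        assert q75 - q25 == pytest.approx(1.0, abs=1e-12)

    def test_outlier_does_not_set_scale(self):
        base = np.array([1.0, 2, 3, 4, 5, 6, 7, 8])
        spiked = base.copy()
        spiked[-1] = 1000.0
        rob = rp.robust_normalize(spiked)
        # min-max scaling would crush the non-outlier spread to ~0.007;
        # robust scaling keeps it of order 1
        minmax = (spiked - spiked.min()) / np.ptp(spiked)
        assert np.ptp(rob[:-1]) > 1.0
        assert np.ptp(minmax[:-1]) < 0.01

    def test_flat_signal_raises(self):
        with pytest.raises(rp.FlatSignalError):
            rp.robust_normalize(np.zeros(4))

    def test_too_short_raises(self):
        with pytest.raises(rp.DataError):
            rp.robust_normalize(np.array([1.0, 2.0]))


class TestResampleTo:
    def test_identity_at_equal_rates(self, rng):
        x = rng.normal(size=100)
        assert np.array_equal(rp.resample_to(x, 30, 30), x)

    def test_preserves_dominant_frequency(self):
        t = np.arange(0, 20, 1 / 30)
        x = np.sin(2 * np.pi * 1.2 * t)
        y = rp.resample_to(x, 30, 60)
        assert dominant_frequency(y, 60) == pytest.approx(1.2, abs=0.02)

    def test_exact_on_linear_ramp(self):
        x = np.linspace(0, 5, 151)  # 5 s at 30 Hz (+1 sample)
        y = rp.resample_to(x, 30, 60)
        t_out = np.arange(len(y)) / 60
        assert np.allclose(y, t_out, atol=1e-9)
        assert y[0] == x[0]

    def test_duration_preserved_within_one_sample(self):
        x = np.zeros(150)
        y = rp.resample_to(x, 25, 60)
        assert abs(len(y) / 60 - 150 / 25) <= 1 / 25


class TestDetrend:
    def test_removes_linear_ramp(self):
        ramp = np.linspace(0, 10, 600)
        out = rp.detrend(ramp, fs=60)
        assert np.max(np.abs(out)) < 1e-6 * np.ptp(ramp)

    def test_preserves_cardiac_band_sinusoid(self):
        t = np.arange(0, 10, 1 / 60)
        sine = np.sin(2 * np.pi * 1.2 * t)
        out = rp.detrend(sine + 3 * t, fs=60)
        # recovered amplitude within 5% (compare sine component power)
        amp = np.sqrt(2 * np.mean(out ** 2))
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_constant_maps_to_zero(self):
        out = rp.detrend(np.full(100, 3.5), fs=60)
        assert np.allclose(out, 0.0, atol=1e-9)

    def test_zero_mean_output(self, rng):
        out = rp.detrend(rng.normal(size=500) + 5, fs=60)
        assert out.mean() == pytest.approx(0.0, abs=1e-12)

    def test_linear_method_available(self):
        ramp = np.linspace(0, 1, 100)
        out = rp.detrend(ramp, fs=60, method="linear")
        assert np.max(np.abs(out)) < 1e-9


class TestBandpass:
    def test_passband_tone_nearly_unattenuated(self):
        t = np.arange(0, 30, 1 / 60)
        x = np.sin(2 * np.pi * 1.2 * t)
        y = rp.bandpass(x, fs=60)
        # compare RMS in the central region (avoid filter edge transients)
        sl = slice(300, -300)
        gain_db = 20 * np.log10(np.std(y[sl]) / np.std(x[sl]))
        assert gain_db > -1.0

    def test_stopband_tone_heavily_attenuated(self):
        t = np.arange(0, 60, 1 / 60)
        sl = slice(600, -600)
        tones = {}
        for f in (0.2, 1.2):
            x = np.sin(2 * np.pi * f * t)
            tones[f] = np.std(rp.bandpass(x, fs=60)[sl])
        ratio_db = 20 * np.log10(tones[0.2] / tones[1.2])
        assert ratio_db < -20.0

    def test_zero_in_zero_out(self):
        assert np.allclose(rp.bandpass(np.zeros(600), fs=60), 0.0)

    def test_zero_phase(self):
        t = np.arange(0, 30, 1 / 60)
        x = np.sin(2 * np.pi * 1.5 * t)
        y = rp.bandpass(x, fs=60)
        sl = slice(300, -300)
        xs, ys = x[sl] - x[sl].mean(), y[sl] - y[sl].mean()
        lags = correlation_lags(len(xs), len(ys))
        xc = correlate(xs, ys)
        assert lags[np.argmax(xc)] == 0

    def test_rejects_low_sampling_rate(self):
        with pytest.raises(rp.ConfigError):
            rp.bandpass(np.zeros(100), fs=8)


class TestSegmentWindows:
    def _traces(self, dur, fs=60):
        n = int(dur * fs)
        x = np.arange(n, dtype=float)
        rgb = rp.RGBTrace(red=x, green=x, blue=x, fs=fs)
        cppg = rp.ContactTrace(samples=x, fs=fs)
        return rgb, cppg

    def test_sixty_seconds_gives_six_windows_per_channel(self):
        pairs = rp.segment_windows(*self._traces(60))
        assert len(pairs) == 18
        per_channel = {}
        for p in pairs:
            per_channel.setdefault(p.channel, []).append(p)
            assert p.duration_s == pytest.approx(10.0)
        assert all(len(v) == 6 for v in per_channel.values())

    def test_windows_do_not_overlap_and_align(self):
        pairs = [p for p in rp.segment_windows(*self._traces(60))
                 if p.channel == "green"]
        for p in pairs:
            assert p.x[0] == p.window_index * 600  # sample index = timestamp
            assert np.array_equal(p.x, p.y)

    def test_trailing_seconds_dropped(self):
        pairs = rp.segment_windows(*self._traces(65))
        assert len(pairs) == 18

    def test_too_short_raises(self):
        with pytest.raises(rp.DataError):
            rp.segment_windows(*self._traces(8))


class TestPreprocessPair:
    def test_noise_free_green_matches_cppg(self, noise_free_scene):
        pairs = rp.preprocess_pair(noise_free_scene.rgb, noise_free_scene.cppg)
        green = [p for p in pairs if p.channel == "green"]
        assert len(green) == 6
        for p in green:
            assert rp.pearson_r(p.x, p.y) > 0.99

    def test_flat_channel_error_carries_identity(self):
        n = 60 * 30
        flat = np.zeros(n)
        t = np.arange(n) / 30
        wave = np.sin(2 * np.pi * 1.2 * t)
        rgb = rp.RGBTrace(red=flat, green=wave, blue=wave, fs=30)
        cppg = rp.ContactTrace(samples=np.sin(2 * np.pi * 1.2 * np.arange(3600) / 60),
                               fs=60)
        with pytest.raises(rp.FlatSignalError) as exc_info:
            rp.preprocess_pair(rgb, cppg, subject="S07", activity="Gym")
        assert exc_info.value.channel == "red"
        assert exc_info.value.subject == "S07"

    def test_stage_order_is_pinned(self, noise_free_scene):
        """Normalization precedes filtering: filtering first changes output."""
        cfg = rp.PreprocessConfig()
        pairs = rp.preprocess_pair(noise_free_scene.rgb, noise_free_scene.cppg, cfg)
        ref = [p for p in pairs if p.channel == "green"][0].x

        # swapped order: bandpass the raw channel, then normalize
        raw = noise_free_scene.rgb.green
        swapped = rp.robust_normalize(rp.bandpass(
            rp.resample_to(raw, 30, 60), fs=60))
        swapped = rp.detrend(swapped, fs=60)[:len(ref)]
        assert not np.allclose(ref, swapped[:len(ref)], atol=1e-3)

    def test_channel_subset(self, noise_free_scene):
        pairs = rp.preprocess_pair(noise_free_scene.rgb, noise_free_scene.cppg,
                                   channels=("green",))
        assert {p.channel for p in pairs} == {"green"}
        assert len(pairs) == 6

    def test_common_rate_configurable_to_camera_rate(self, noise_free_scene):
        cfg = rp.PreprocessConfig(common_fs=30.0)
        pairs = rp.preprocess_pair(noise_free_scene.rgb, noise_free_scene.cppg, cfg)
        assert all(p.fs_common == 30.0 for p in pairs)
        assert all(len(p.x) == 300 for p in pairs)
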