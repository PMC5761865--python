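"""FSI chain: normalization, wavelet filter, envelopes, subareas, index."""

import numpy as np
import pytest

from fetalstress.ecg_rr import RRSeries, Tachogram
from fetalstress.fsi_core import (
    FilteredWindow,
    FSIConfig,
    InvalidWindow,
    envelopes,
    fsi_from_rr,
    fsi_inst,
    fsi_series,
    highpass_hf,
    normalize_window,
    subarea_areas,
    summarize_window,
)
from fetalstress.synth import RRSimParams, simulate_rr

from .conftest import fft_peak_amplitude

FS = 8.0


def tach_from(values, rate=FS, start=0.0):
    return Tachogram(rate=rate, values=np.asarray(values, dtype=float), start_time=start)


def sine_window(freq, amp, n=512, fs=FS, phase=0.0):
    t = np.arange(n) / fs
    return amp * np.sin(2 * np.pi * freq * t + phase)


class TestNormalize:
    def test_constant_window_is_zero(self, cfg):
        tach = tach_from(np.full(600, 600.0))
        out = normalize_window(tach, 0.0, cfg)
        np.testing.assert_allclose(out, 0.0, atol=1e-15)
        assert out.mean() == 0.0

    def test_alternating_window(self, cfg):
        vals = np.tile([500.0, 700.0], 300)
        out = normalize_window(tach_from(vals), 0.0, cfg)
        np.testing.assert_allclose(np.unique(np.round(out, 12)), [-1 / 6, 1 / 6])

    def test_sine_fractional_amplitude(self, cfg):
        t = np.arange(512) / FS
        vals = 375.0 + 20.0 * np.sin(2 * np.pi * 0.25 * t)
        out = normalize_window(tach_from(vals), 0.0, cfg)
        assert np.max(out) == pytest.approx(20.0 / 375.0, rel=0.01)

    def test_uncovered_window_signals_invalid(self, cfg):
        with pytest.raises(InvalidWindow):
            normalize_window(tach_from(np.full(100, 600.0)), 0.0, cfg)


class TestFilter:
    def test_dc_removed(self, cfg):
        out = highpass_hf(np.full(512, 3.7), cfg)
        assert np.max(np.abs(out.values)) <= 1e-6

    def test_hf_tone_passes(self, cfg):
        out = highpass_hf(sine_window(0.40, 1.0), cfg)
        assert fft_peak_amplitude(out.values, FS, 0.40) >= 0.7

    def test_lf_tone_blocked(self, cfg):
        out = highpass_hf(sine_window(0.05, 1.0), cfg)
        assert fft_peak_amplitude(out.values, FS, 0.05) <= 0.1

    def test_filtered_window_near_zero_mean(self, cfg):
        out = highpass_hf(sine_window(0.40, 0.05), cfg)
        assert abs(np.mean(out.values)) < 1e-6 * np.max(np.abs(out.values))


class TestEnvelopes:
    def test_stationary_sine_envelopes(self, cfg):
        a = 0.05
        fw = FilteredWindow(0.0, sine_window(0.25, a), FS)
        env = envelopes(fw)
        # window interior, away from the flat edge extension
        t = np.linspace(4.0, 60.0, 200)
        np.testing.assert_allclose(env.upper(t), a, rtol=0.02)
        np.testing.assert_allclose(env.lower(t), -a, rtol=0.02)
        assert np.all(env.upper(t) >= env.lower(t))

    def test_flat_window_degenerate(self):
        with pytest.raises(InvalidWindow):
            envelopes(FilteredWindow(0.0, np.zeros(512), FS))

    def test_ramping_amplitude_tracked(self, cfg):
        t = np.arange(512) / FS
        a0 = 0.05
        amp = a0 * (1.0 + t / 64.0)  # A -> 2A across the window
        fw = FilteredWindow(0.0, amp * np.sin(2 * np.pi * 0.25 * t), FS)
        env = envelopes(fw)
        seg = 64.0 / 4
        mids = np.array([seg * (k + 0.5) for k in range(4)])
        expected = a0 * (1.0 + mids / 64.0)
        np.testing.assert_allclose(env.upper(mids), expected, rtol=0.05)


class TestSubareas:
    @pytest.mark.parametrize("a", [0.02, 0.05, 0.10])
    def test_closed_form_sine_area(self, cfg, a):
        # each 16 s segment of a stationary sine has area 2A * 16
        fw = FilteredWindow(0.0, sine_window(0.25, a), FS)
        areas = subarea_areas(envelopes(fw), cfg)
        np.testing.assert_allclose(areas.areas, 2 * a * 16.0, rtol=0.05)
        assert areas.auc_min == np.min(areas.areas)
        assert areas.auc_min <= np.mean(areas.areas)

    def test_half_amplitude_step(self, cfg):
        t = np.arange(512) / FS
        amp = np.where(t < 32.0, 0.05, 0.10)
        fw = FilteredWindow(0.0, amp * np.sin(2 * np.pi * 0.25 * t), FS)
        areas = subarea_areas(envelopes(fw), cfg)
        # the minimum comes from a first-half segment
        assert areas.auc_min == pytest.approx(2 * 0.05 * 16.0, rel=0.10)

    def test_noise_windows_respect_min_le_mean(self, cfg):
        rng = np.random.default_rng(4)
        for _ in range(20):
            x = highpass_hf(0.02 * rng.standard_normal(512), cfg)
            areas = subarea_areas(envelopes(x), cfg)
            assert areas.auc_min <= np.mean(areas.areas) + 1e-12
            assert np.all(areas.areas >= 0)


class TestFsiInst:
    @pytest.mark.parametrize(
        "auc, expected",
        [(0.0, 9.375), (1.0, 100 * 6.3 / 12.8), (3.0, 100.0)],
    )
    def test_affine_map_and_clamp(self, cfg, auc, expected):
        assert fsi_inst(auc, cfg) == pytest.approx(expected, rel=1e-6)

    def test_negative_auc_rejected(self, cfg):
        with pytest.raises(ValueError):
            fsi_inst(-0.1, cfg)


def _constant_rr(duration_s=600.0, rr_ms=600.0):
    n = int(duration_s / (rr_ms / 1000.0))
    iv = np.full(n, rr_ms)
    return RRSeries(beat_times=np.cumsum(iv) / 1000.0, intervals=iv)


class TestFsiSeries:
    def test_constant_rr_fixed_point(self, cfg):
        series = fsi_from_rr(_constant_rr(), cfg)
        t, v = series.averaged
        assert len(v) > 300
        np.testing.assert_allclose(v, 100 * cfg.b / cfg.denom)
        assert np.all(t >= series.warmup_end - 1e-9)

    def test_stationary_tone_gives_stationary_fsi(self, cfg):
        t = np.arange(0, 600.0, 1 / FS)
        vals = 500.0 * (1.0 + 0.04 * np.sin(2 * np.pi * 0.4 * t))
        _, v = fsi_series(tach_from(vals), cfg).averaged
        assert np.ptp(v) / np.median(v) < 0.02

    def test_amplitude_step_raises_fsi(self, cfg):
        t = np.arange(0, 1200.0, 1 / FS)
        gain = np.where(t < 600.0, 1.0, 2.0)
        vals = 600.0 * (1.0 + 0.03 * gain * np.sin(2 * np.pi * 0.4 * t))
        series = fsi_series(tach_from(vals), cfg)
        tt, vv = series.averaged
        before = vv[(tt > 500) & (tt <= 590)].mean()
        after = vv[(tt > 1100) & (tt <= 1190)].mean()
        assert after > before * 1.2

    def test_monotone_in_hf_amplitude(self, cfg):
        medians = []
        for a in (0.01, 0.02, 0.03, 0.04, 0.05):
            rr = simulate_rr(RRSimParams(mean_rr=500.0, hf_amp=a, duration=420.0, seed=11))
            _, v = fsi_from_rr(rr, cfg).averaged
            medians.append(np.median(v))
        assert np.all(np.diff(medians) > 0)
        assert max(medians) < 100.0  # pre-clamp regime

    def test_mean_rate_invariance(self, cfg):
        # identical fractional modulation at two mean rates: the window
        # normalization divides out the mean, so the index is unchanged
        t = np.arange(0, 420.0, 1 / FS)
        meds = []
        for rr_ms in (600.0, 400.0):
            vals = rr_ms * (1.0 + 0.03 * np.sin(2 * np.pi * 0.4 * t))
            _, v = fsi_series(tach_from(vals), cfg).averaged
            meds.append(np.median(v))
        assert abs(meds[0] - meds[1]) / meds[0] < 0.03

    def test_frequency_selectivity(self, cfg):
        floor = 100 * cfg.b / cfg.denom
        rr_lf = simulate_rr(RRSimParams(mean_rr=500.0, hf_amp=0.0, lf_amp=0.04,
                                        lf_freq=0.05, duration=420.0, seed=15))
        _, v_lf = fsi_from_rr(rr_lf, cfg).averaged
        rr_hf = simulate_rr(RRSimParams(mean_rr=500.0, hf_amp=0.04, hf_freq=0.40,
                                        duration=420.0, seed=15))
        _, v_hf = fsi_from_rr(rr_hf, cfg).averaged
        assert np.median(v_lf) == pytest.approx(floor, rel=0.10)
        assert np.median(v_hf) > np.median(v_lf)

    def test_time_shift_invariance(self, cfg):
        def run(duration, shift):
            t = np.arange(0, duration, 1 / FS) - shift
            vals = 500.0 * (1.0 + 0.03 * np.sin(2 * np.pi * 0.4 * t))
            return fsi_series(tach_from(vals), cfg)

        base = run(420.0, 0.0)
        shifted = run(450.0, 30.0)  # same signal with 30 s prepended
        _, v0 = base.averaged
        _, v1 = shifted.averaged
        assert abs(np.median(v1) - np.median(v0)) / np.median(v0) < 0.01

    def test_too_short_signal(self, cfg):
        with pytest.raises(ValueError, match="signal too short"):
            fsi_series(tach_from(np.full(100, 500.0)), cfg)


class TestSummarize:
    def _series(self, cfg):
        return fsi_from_rr(_constant_rr(700.0), cfg)

    def test_summary_of_constant_series(self, cfg):
        s = self._series(cfg)
        w = summarize_window(s, 300.0, 600.0)
        assert w.fsi_min == w.fsi_max == w.fsi_mean == pytest.approx(9.375)
        assert w.fsi_min <= w.fsi_mean <= w.fsi_max

    def test_window_before_warmup_errors(self, cfg):
        s = self._series(cfg)
        with pytest.raises(ValueError, match="empty summary window"):
            summarize_window(s, 0.0, 60.0)

    def test_degenerate_interval_errors(self, cfg):
        s = self._series(cfg)
        with pytest.raises(ValueError):
            summarize_window(s, 400.0, 400.0)
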