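"""Unit and property tests for the camera-PPG heart-rate estimator."""

import numpy as np
import pytest
from scipy import signal

from pulsefit.config import HrConfig
from pulsefit.errors import ConfigurationError, InsufficientDataError, ValidationError
from pulsefit.ppg import (
    ChannelSeries,
    compute_acf,
    confidence_score,
    estimate_window_hr,
    hr_timecourse,
    preprocess,
    resample_uniform,
    retained_fraction,
    split_windows,
)
from pulsefit.simulate import ConstantHR, PpgSimSpec, simulate_ppg

from conftest import clean_window, make_series


class TestResampleUniform:
    def test_identity_on_uniform_series(self):
        x = np.sin(2 * np.pi * 1.3 * np.arange(600) / 60.0)
        s = make_series(x)
        out = resample_uniform(s, 60.0)
        assert np.allclose(out.green, x, atol=1e-12)
        assert np.allclose(np.diff(out.timestamps), 1 / 60.0)

    def test_two_point_linear_interpolation(self):
        s = ChannelSeries([0.0, 1.0], [0.0, 60.0], [0.0, 60.0], [0.0, 60.0], 1.0)
        out = resample_uniform(s, 4.0)
        assert np.allclose(out.green, [0.0, 15.0, 30.0, 45.0, 60.0])
        assert np.allclose(out.timestamps, [0.0, 0.25, 0.5, 0.75, 1.0])

    def test_jittered_sinusoid_matches_analytic_oracle(self):
        rng = np.random.default_rng(3)
        t = np.sort(np.arange(0, 10, 1 / 60.0) + rng.uniform(-4e-3, 4e-3, 600))
        f = 1.2
        x = np.sin(2 * np.pi * f * t)
        s = ChannelSeries(t, x, x, x, 60.0)
        out = resample_uniform(s, 60.0)
        oracle = np.sin(2 * np.pi * f * out.timestamps)
        rms = np.sqrt(np.mean((out.green - oracle) ** 2))
        # linear interpolation error bound for jitter << sampling interval
        assert rms < 0.01

    def test_too_short_series_rejected(self):
        with pytest.raises(ValidationError):
            resample_uniform(ChannelSeries([0.0], [1.0], [1.0], [1.0], 60.0), 60.0)

    def test_non_monotone_timestamps_rejected(self):
        with pytest.raises(ValidationError, match="strictly increasing"):
            ChannelSeries([0.0, 0.1, 0.1], [1, 2, 3], [1, 2, 3], [1, 2, 3], 60.0)


class TestPreprocess:
    def test_constant_series_maps_to_zero(self):
        out = preprocess(make_series(np.full(600, 200.0)))
        assert np.allclose(out.green, 0.0, atol=1e-9)

    def test_offset_removed_passband_amplitude_preserved(self):
        rate, f = 60.0, 1.5
        t = np.arange(1200) / rate
        s = make_series(100.0 + np.sin(2 * np.pi * f * t), rate)
        out = preprocess(s, band=(0.6, 4.0))
        assert abs(np.mean(out.green)) < 1e-6
        # oracle: squared magnitude response of the zero-phase filter at f
        sos = signal.butter(4, [0.6, 4.0], btype="bandpass", fs=rate, output="sos")
        _, h = signal.sosfreqz(sos, worN=[f], fs=rate)
        expected_gain = np.abs(h[0]) ** 2
        amp = 2 * np.abs(np.fft.rfft(out.green))[np.argmin(
            np.abs(np.fft.rfftfreq(1200, 1 / rate) - f))] / 1200
        assert amp == pytest.approx(expected_gain, rel=0.05)
        assert amp == pytest.approx(1.0, rel=0.05)

    def test_drift_attenuated_at_least_20_db(self):
        rate = 60.0
        sos = signal.butter(4, [0.6, 4.0], btype="bandpass", fs=rate, output="sos")
        _, h = signal.sosfreqz(sos, worN=[0.1, 1.5], fs=rate)
        gain_drift, gain_sig = np.abs(h) ** 2  # zero-phase doubles attenuation
        assert 20 * np.log10(gain_sig / gain_drift) >= 20.0
        # empirical check on a composite signal
        t = np.arange(3600) / rate
        s = make_series(5 * np.sin(2 * np.pi * 0.1 * t) + np.sin(2 * np.pi * 1.5 * t), rate)
        out = preprocess(s)
        spec = np.abs(np.fft.rfft(out.green))
        freqs = np.fft.rfftfreq(3600, 1 / rate)
        a_drift = spec[np.argmin(np.abs(freqs - 0.1))] / 5
        a_sig = spec[np.argmin(np.abs(freqs - 1.5))]
        assert 20 * np.log10(a_sig / a_drift) >= 20.0

    def test_band_outside_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            preprocess(make_series(np.zeros(100), rate=4.0), band=(0.6, 4.0))


class TestSplitWindows:
    @pytest.mark.parametrize("seconds,n_expected", [(60, 6), (20, 2), (25, 2)])
    def test_window_count(self, seconds, n_expected):
        s = make_series(np.zeros(int(seconds * 60)))
        wins = split_windows(s, 10.0)
        assert len(wins) == n_expected
        assert all(len(w) == 600 for w in wins)

    def test_too_short_capture_raises(self):
        with pytest.raises(InsufficientDataError):
            split_windows(make_series(np.zeros(300)), 10.0)


class TestComputeAcf:
    def test_sinusoid_fundamental_at_period(self):
        t = np.arange(600) / 60.0
        acf = compute_acf(np.sin(2 * np.pi * 1.0 * t), 60.0)
        assert acf.fundamental_lag == pytest.approx(60.0, abs=0.5)

    def test_white_noise_rarely_yields_candidates(self):
        rng = np.random.default_rng(11)
        cfg = HrConfig()
        n_with = 0
        for _ in range(100):
            x = rng.normal(0, 1, 600)
            filt = preprocess(make_series(128 + x), cfg.band)
            acf = compute_acf(filt.green, 60.0, peak_threshold=cfg.peak_threshold)
            n_with += bool(acf.candidate_peaks)
        assert n_with / 100 < 0.3  # candidate rate well below 1

    def test_harmonic_rich_pulse_resolves_fundamental_not_harmonic(self):
        # 60 bpm pulse with a strong 2nd harmonic: the half-period ACF value
        # must not beat the full-period peak
        w = clean_window(60.0)
        acf = compute_acf(w.green, 60.0)
        hr = 60.0 * 60.0 / acf.fundamental_lag
        assert hr == pytest.approx(60.0, abs=1.0)
        period = int(round(acf.fundamental_lag))
        assert acf.acf_values[period] > acf.acf_values[period // 2]

    def test_lag_bounds_cover_supported_range(self):
        w = clean_window(75.0)
        acf = compute_acf(w.green, 60.0, hr_min=45, hr_max=210)
        lo, hi = acf.lag_bounds
        assert 60.0 * 60.0 / lo >= 210.0  # shortest lag representable as >= hr_max
        assert 60.0 * 60.0 / hi <= 45.0
        assert all(lo <= k <= hi for k, _ in acf.candidate_peaks)

    def test_constant_window_has_no_fundamental(self):
        acf = compute_acf(np.zeros(600), 60.0)
        assert acf.fundamental_lag is None
        assert confidence_score(acf) == 0.0


class TestConfidence:
    def test_noiseless_sinusoid_high_confidence(self):
        w = clean_window(75.0)
        acf = compute_acf(w.green, 60.0)
        assert confidence_score(acf) >= 0.9

    def test_confidence_amplitude_invariant(self):
        w = clean_window(90.0)
        c1 = confidence_score(compute_acf(w.green, 60.0))
        c2 = confidence_score(compute_acf(17.3 * w.green, 60.0))
        assert c1 == pytest.approx(c2, abs=1e-12)

    def test_median_confidence_non_increasing_in_noise(self):
        medians = []
        for noise in (0.5, 3.0, 12.0):
            scores = []
            for seed in range(50):
                w = clean_window(80.0, noise_sd=noise, seed=seed)
                scores.append(confidence_score(compute_acf(w.green, 60.0)))
            medians.append(np.median(scores))
        assert medians[0] >= medians[1] >= medians[2]

    def test_peak_ratio_diagnostic_at_least_one(self):
        w = clean_window(75.0)
        acf = compute_acf(w.green, 60.0)
        assert acf.peak_ratio >= 1.0


class TestEstimateWindow:
    def test_fusion_selects_signal_channel(self, hr_config):
        rng = np.random.default_rng(2)
        t = np.arange(600) / 60.0
        green = 128 + 10 * np.sin(2 * np.pi * 1.25 * t)
        red = 128 + rng.normal(0, 3, 600)
        s = ChannelSeries(t, red, green, np.full(600, 128.0), 60.0)
        w = split_windows(preprocess(resample_uniform(s), hr_config.band), 10.0)[0]
        est = estimate_window_hr(w, hr_config)
        assert est.source_channel == "green"
        assert est.fused_hr_bpm == pytest.approx(75.0, abs=1.0)
        assert est.valid

    def test_identical_channels_tie_breaks_to_green(self, hr_config):
        w = clean_window(100.0)
        est = estimate_window_hr(w, hr_config)
        assert est.source_channel == "green"
        assert est.confidence["red"] == pytest.approx(est.confidence["green"])

    def test_fused_equals_argmax_channel(self, hr_config):
        for seed in range(5):
            w = clean_window(70 + 10 * seed, noise_sd=2.0, seed=seed)
            est = estimate_window_hr(w, hr_config)
            if est.source_channel == "none":
                continue
            assert est.fused_hr_bpm == est.hr_bpm[est.source_channel]
            assert est.fused_confidence == max(est.confidence["red"],
                                               est.confidence["green"])
            assert hr_config.hr_min <= est.fused_hr_bpm <= hr_config.hr_max
            assert 0.0 <= est.fused_confidence <= 1.0

    def test_no_fundamental_in_either_channel(self, hr_config):
        w = split_windows(make_series(np.zeros(600)), 10.0)[0]
        est = estimate_window_hr(w, hr_config)
        assert est.source_channel == "none"
        assert not est.valid
        assert est.fused_confidence == 0.0


class TestTimecourse:
    def test_clean_capture_full_retention(self, hr_config):
        spec = PpgSimSpec(duration=60.0, hr_profile=ConstantHR(72.0), seed=4)
        series, truth = simulate_ppg(spec)
        ests = hr_timecourse(series, hr_config)
        assert len(ests) == 6
        assert retained_fraction(ests) == 1.0
        for e, tr in zip(ests, truth):
            assert e.fused_hr_bpm == pytest.approx(tr, abs=1.0)

    def test_noise_windows_lower_retention(self, hr_config):
        spec = PpgSimSpec(duration=60.0, hr_profile=ConstantHR(72.0), seed=4)
        series, _ = simulate_ppg(spec)
        rng = np.random.default_rng(9)
        for name in ("red", "green", "blue"):
            ch = series.channel(name)
            ch[:1200] = 128 + rng.normal(0, 3, 1200)  # first two windows pure noise
        ests = hr_timecourse(series, hr_config)
        assert retained_fraction(ests) == pytest.approx(4 / 6)

    def test_constant_capture_zero_retention(self, hr_config):
        ests = hr_timecourse(make_series(np.full(3600, 128.0)), hr_config)
        assert len(ests) == 6
        assert retained_fraction(ests) == 0.0

    def test_retention_non_increasing_in_cutoff(self):
        spec = PpgSimSpec(duration=60.0, hr_profile=ConstantHR(100.0),
                          noise_sd=6.0, seed=13)
        series, _ = simulate_ppg(spec)
        fracs = []
        for cutoff in (0.0, 0.25, 0.5, 0.75, 1.0):
            ests = hr_timecourse(series, HrConfig(confidence_cutoff=cutoff))
            fracs.append(retained_fraction(ests))
        assert all(a >= b for a, b in zip(fracs, fracs[1:]))
        assert fracs[0] == 1.0
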