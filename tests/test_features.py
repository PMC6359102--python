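import numpy as np
import pandas as pd
import pytest

from stressvr.features import (
    FEATURE_COLUMNS,
    apply_scaler,
    derivative_stats,
    detect_extrema,
    extract_features,
    fit_scaler,
    gsr_peak_features,
    ibi_features,
    third_order_cumulant,
    wavelet_packet_split,
)
from stressvr.signal_io import WindowedSegment
from stressvr.simulate import gen_bvp_signal, gen_gsr_signal

from oracles import brute_third_order_cumulant


class TestWaveletPacketSplit:
    @pytest.mark.parametrize("n", [64, 100, 333, 1024, 4096])
    def test_band_additivity(self, n, rng):
        x = rng.normal(size=n)
        bp = wavelet_packet_split(x, "db4", 3)
        np.testing.assert_allclose(bp.low + bp.high, x, rtol=1e-8, atol=1e-10)

    def test_slow_sinusoid_energy_concentrates_in_low_band(self):
        t = np.arange(0, 4, 1 / 128)
        x = np.sin(2 * np.pi * 0.5 * t)
        bp = wavelet_packet_split(x, "db4", 5)
        assert np.sum(bp.low**2) / np.sum(x**2) > 0.95

    def test_white_noise_energy_splits_by_band_count(self):
        # flat spectrum: the lowest of 2^level packets holds ~2^-level of
        # the energy, so the high band carries about 1 - 2^-level
        level = 5
        fracs = []
        for seed in range(50):
            x = np.random.default_rng(seed).normal(size=1280)
            bp = wavelet_packet_split(x, "db4", level)
            fracs.append(np.sum(bp.high**2) / np.sum(x**2))
        assert abs(np.mean(fracs) - (1 - 2.0**-level)) < 0.02

    def test_too_short_signal_suggests_smaller_level(self):
        with pytest.raises(ValueError, match="level"):
            wavelet_packet_split(np.zeros(12), "db4", 2)


class TestDetectExtrema:
    def test_constant_signal_has_no_strict_extrema(self):
        assert len(detect_extrema(np.ones(50), "maxima")) == 0

    def test_sinusoid_maxima_spacing(self):
        fs, period = 128.0, 0.8
        t = np.arange(0, 3, 1 / fs)
        x = np.sin(2 * np.pi * t / period)
        peaks = detect_extrema(x, "maxima", min_separation=int(0.3 * fs))
        assert len(peaks) in (3, 4)
        spacing = np.diff(peaks)
        assert np.all(np.abs(spacing - period * fs) <= 2)

    def test_single_spike(self):
        x = np.zeros(21)
        x[7] = 1.0
        np.testing.assert_array_equal(detect_extrema(x, "maxima"), [7])

    def test_close_extrema_keep_the_more_extreme(self):
        x = np.zeros(20)
        x[5], x[8] = 1.0, 2.0  # 3 apart; separation 5 keeps the higher one
        np.testing.assert_array_equal(detect_extrema(x, "maxima", min_separation=5), [8])

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            detect_extrema(np.zeros(2), "maxima")


class TestIbiFeatures:
    def test_recovers_configured_ibi_from_pulse_train(self):
        rec = gen_bvp_signal(0.0, duration=3.0, seed=7, base_ibi=0.8, ibi_jitter_sd=0.0, noise_sd=0.0)
        low = wavelet_packet_split(rec.samples, "db4", 3).low
        mean, sd = ibi_features(low, 128.0)
        assert 0.76 <= mean <= 0.84
        assert sd < 0.02

    def test_two_diastolic_points_give_zero_sd(self):
        t = np.arange(0, 2, 1 / 128)
        x = np.cos(2 * np.pi * t)  # minima at 0.5 s and 1.5 s
        mean, sd = ibi_features(x, 128.0)
        assert sd == 0.0
        assert abs(mean - 1.0) < 0.02

    def test_flat_signal_raises_insufficient_beats(self):
        with pytest.raises(ValueError, match="insufficient beats"):
            ibi_features(np.zeros(384), 128.0)


class TestThirdOrderCumulant:
    def test_pure_sinusoid_zero_lag_is_zero(self):
        # full periods: the third moment of a sinusoid vanishes exactly
        t = np.arange(512) / 128.0  # 4 s window, 2 Hz -> 8 complete cycles
        for phase in (0.0, 0.7, 2.1):
            x = np.sin(2 * np.pi * 2.0 * t + phase)
            assert abs(third_order_cumulant(x)) < 1e-6

    def test_matches_hand_computed_example(self):
        x = [1.0, -1.0, 2.0, 0.0]
        assert third_order_cumulant(x, (0, 0)) == pytest.approx(
            brute_third_order_cumulant(x, (0, 0)), abs=1e-12
        )

    def test_constant_is_zero(self):
        assert third_order_cumulant(np.full(32, 3.7)) == 0.0

    def test_matches_brute_force_over_random_lags(self, rng):
        for _ in range(20):
            n = int(rng.integers(16, 257))
            x = rng.normal(size=n)
            lags = (int(rng.integers(-4, 5)), int(rng.integers(-4, 5)))
            assert third_order_cumulant(x, lags) == pytest.approx(
                brute_third_order_cumulant(x, lags), abs=1e-10
            )

    def test_excessive_lag_rejected(self):
        with pytest.raises(ValueError, match="lag"):
            third_order_cumulant(np.zeros(4), (5, 0))


class TestGsrPeakFeatures:
    def test_monotone_ramp_has_no_peaks(self):
        assert gsr_peak_features(np.linspace(0, 1, 60), 4.0) == (0, 0.0)

    def test_single_triangular_bump(self):
        x = np.zeros(41)
        x[18:23] = [0.5, 1.5, 3.0, 1.5, 0.5]
        count, amp = gsr_peak_features(x, 4.0)
        assert count == 1
        assert amp == pytest.approx(3.0, abs=1e-9)

    def test_injected_scrs_counted(self):
        rec = gen_gsr_signal(0.5, duration=30.0, seed=3, event_times=[4.0, 14.0, 24.0], noise_sd=0.0, drift_sd=0.0)
        count, amp = gsr_peak_features(rec.samples, 4.0)
        assert count == 3
        assert amp > 0


class TestDerivativeStats:
    def test_linear_ramp(self):
        fs, a = 4.0, 0.7
        x = a * np.arange(20) / fs
        d1m, d1s, d2m, d2s, neg = derivative_stats(x, fs)
        assert d1m == pytest.approx(a)
        assert d1s == pytest.approx(0.0, abs=1e-12)
        assert d2m == pytest.approx(0.0, abs=1e-9)
        assert neg == 0.0

    def test_strictly_decreasing_sequence(self):
        _, _, _, _, neg = derivative_stats(-np.arange(10.0), 4.0)
        assert neg == 1.0

    def test_matches_elementwise_oracle(self, rng):
        x = rng.normal(size=40)
        fs = 4.0
        d1 = (x[1:] - x[:-1]) * fs
        d2 = (d1[1:] - d1[:-1]) * fs
        got = derivative_stats(x, fs)
        expected = (d1.mean(), d1.std(), d2.mean(), d2.std(), np.mean(d1 < 0))
        np.testing.assert_allclose(got, expected, atol=1e-12)


def _segment(stress, seed, duration=3.0):
    bvp = gen_bvp_signal(stress, duration=duration, seed=seed)
    gsr = gen_gsr_signal(stress, duration=duration, seed=seed + 500)
    return WindowedSegment(
        channels={"BVP": bvp.samples, "GSR": gsr.samples},
        start=0.0,
        end=duration,
        sampling_rates={"BVP": 128.0, "GSR": 4.0},
    )


class TestExtractFeatures:
    def test_deterministic(self):
        seg = _segment(0.5, 11)
        f1 = extract_features(seg)
        f2 = extract_features(seg)
        assert f1 == f2
        assert set(f1) == set(FEATURE_COLUMNS)

    def test_scr_activity_rises_with_stress(self):
        # compare total GSR peak counts across matched windows; 30 seeds
        high, low = 0.0, 0.0
        for seed in range(30):
            fh = extract_features(_segment(1.0, seed, duration=8.0))
            fl = extract_features(_segment(0.0, seed, duration=8.0))
            high += fh["gsr_peak_count_high"] + fh["gsr_peak_count_low"]
            low += fl["gsr_peak_count_high"] + fl["gsr_peak_count_low"]
        assert high > low

    def test_all_zero_channels_raise(self):
        seg = WindowedSegment(
            channels={"BVP": np.zeros(384), "GSR": np.zeros(12)},
            start=0.0,
            end=3.0,
            sampling_rates={"BVP": 128.0, "GSR": 4.0},
        )
        with pytest.raises(ValueError):
            extract_features(seg)

    def test_missing_channel_raises(self):
        seg = WindowedSegment(
            channels={"BVP": np.zeros(384)}, start=0.0, end=3.0, sampling_rates={"BVP": 128.0}
        )
        with pytest.raises(ValueError, match="both"):
            extract_features(seg)


class TestScaler:
    def test_basic_column_mapping(self):
        table = pd.DataFrame({"a": [2.0, 4.0, 6.0]})
        s = fit_scaler(table)
        np.testing.assert_allclose(apply_scaler(s, table)["a"], [0.0, 0.5, 1.0])

    def test_constant_column_maps_to_zero(self):
        table = pd.DataFrame({"a": [3.0, 3.0, 3.0]})
        out = apply_scaler(fit_scaler(table), table)
        assert (out["a"] == 0.0).all()

    def test_unseen_values_clip(self):
        train = pd.DataFrame({"a": [0.0, 10.0]})
        s = fit_scaler(train)
        out = apply_scaler(s, pd.DataFrame({"a": [-5.0, 15.0]}))
        np.testing.assert_allclose(out["a"], [0.0, 1.0])

    def test_empty_table_rejected(self):
        with pytest.raises(ValueError):
            fit_scaler(pd.DataFrame())
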