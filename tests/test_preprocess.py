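"""Filtering, lag alignment, scaling and windowing behaviour."""

import numpy as np
import pytest

from enosekit.preprocess import (
    FilterConfig,
    estimate_lag,
    fit_scaler,
    kalman_smooth,
    load_windows,
    preprocess_recording,
    save_windows,
    savgol_smooth,
    windowize,
)
from enosekit.simulate import default_array, gen_intermittent, simulate_response


class TestEstimateLag:
    def test_recovers_exact_shift(self):
        x = np.zeros(300)
        x[80:160] = 5.0
        y = np.roll(x, 7)
        assert estimate_lag(x, y, 30) == 7

    def test_zero_lag(self):
        x = np.sin(np.arange(200) / 9.0)
        assert estimate_lag(x, x, 20) == 0

    def test_constant_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_lag(np.ones(100), np.arange(100.0), 10)

    def test_noisy_shift_recovered_in_most_trials(self):
        # SNR 10 on a step signal; the true 7 s shift should dominate
        hits = 0
        for seed in range(100):
            rng = np.random.default_rng(seed)
            x = np.zeros(400)
            x[100:250] = 10.0
            noise_sd = x.std() / np.sqrt(10.0)
            y = np.roll(x, 7) + rng.normal(0, noise_sd, 400)
            hits += estimate_lag(x, y, 25) == 7
        assert hits >= 95


class TestKalman:
    def test_constant_series_is_fixed_point(self):
        z = np.full(50, 3.5)
        np.testing.assert_allclose(kalman_smooth(z, 1e-3, 1.0), z)

    def test_measurement_trust_limit_returns_input(self):
        rng = np.random.default_rng(0)
        z = rng.normal(size=200)
        np.testing.assert_allclose(kalman_smooth(z, 1.0, 1e-12), z,
                                   atol=1e-5)

    def test_variance_reduced_on_noisy_constant(self):
        rng = np.random.default_rng(1)
        z = 5.0 + rng.normal(0, 1, 2000)
        out = kalman_smooth(z, 1e-3, 1.0)
        assert out[200:].var() < z[200:].var()

    def test_nonpositive_parameters_rejected(self):
        with pytest.raises(ValueError):
            kalman_smooth(np.zeros(5), 0.0, 1.0)


class TestSavgol:
    def test_quadratic_reproduced_exactly(self):
        t = np.arange(60.0)
        z = 0.3 * t**2 - 2 * t + 1
        out = savgol_smooth(z, 11, 2)
        np.testing.assert_allclose(out[5:-5], z[5:-5], atol=1e-8)

    def test_linear_five_point_identity(self):
        np.testing.assert_allclose(
            savgol_smooth(np.array([1.0, 2, 3, 4, 5]), 5, 2),
            [1, 2, 3, 4, 5], atol=1e-10)

    def test_noisy_sine_rmse_improves(self):
        rng = np.random.default_rng(2)
        t = np.arange(500)
        clean = np.sin(2 * np.pi * t / 120.0)
        noisy = clean + rng.normal(0, 0.3, 500)
        out = savgol_smooth(noisy, 11, 3)
        assert np.sqrt(np.mean((out - clean) ** 2)) < np.sqrt(
            np.mean((noisy - clean) ** 2))

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            savgol_smooth(np.zeros(5), 11, 3)


class TestPreprocessRecording:
    def test_identity_config_keeps_recording(self, small_recording):
        cfg = FilterConfig(lag_s=0, kalman_q=None, sg_window=1)
        out = preprocess_recording(small_recording, cfg)
        np.testing.assert_array_equal(out.channels, small_recording.channels)

    def test_filtering_reduces_mse_to_clean_twin(self):
        quiet = default_array({"*": {"noise_sd": 0.0, "drift_walk_sd": 0.0,
                                     "carryover": 0.0}})
        profile = gen_intermittent(2, seed=3)
        clean = simulate_response(profile, quiet, drift_on=False)
        noisy = simulate_response(profile, default_array(), seed=4,
                                  drift_on=False)
        filtered = preprocess_recording(noisy, FilterConfig())
        assert (np.mean((filtered.channels - clean.channels) ** 2)
                < np.mean((noisy.channels - clean.channels) ** 2))

    def test_lag_shift_realigns_response(self):
        # build a channel that is exactly the truth delayed by 7 s
        profile = gen_intermittent(2, seed=5)
        rec = simulate_response(profile, default_array(
            {"*": {"noise_sd": 0.0, "drift_walk_sd": 0.0}}), drift_on=False)
        j = int(np.argmax(profile.conc.var(axis=0)))
        truth = profile.conc[:, j]
        delayed = np.roll(truth * 40 + 400, 7)
        rec.channels[:, 0] = delayed
        cfg = FilterConfig(lag_s=7, kalman_q=None, sg_window=1)
        out = preprocess_recording(rec, cfg)
        assert estimate_lag(truth, out.channels[:, 0], 20) == 0

    def test_no_nans_and_shape_preserved(self, small_recording):
        out = preprocess_recording(small_recording, FilterConfig())
        assert out.channels.shape == small_recording.channels.shape
        assert not np.isnan(out.channels).any()


class TestScaler:
    def test_forced_mapping(self):
        scaler = fit_scaler(np.array([[0.0], [5.0], [10.0]]))
        np.testing.assert_allclose(
            scaler.transform(np.array([[0.0], [5.0], [10.0]])).ravel(),
            [0.0, 0.5, 1.0])

    def test_round_trip_identity(self, rng):
        data = rng.normal(size=(40, 6)) * 100
        scaler = fit_scaler(data)
        np.testing.assert_allclose(
            scaler.inverse_transform(scaler.transform(data)), data,
            atol=1e-12)

    def test_train_extremes_map_to_unit_interval_exactly(self, rng):
        data = rng.normal(size=(30, 4))
        scaler = fit_scaler(data)
        out = scaler.transform(data)
        np.testing.assert_allclose(out.min(axis=0), 0.0, atol=1e-15)
        np.testing.assert_allclose(out.max(axis=0), 1.0, atol=1e-15)

    def test_out_of_range_values_not_clipped(self):
        scaler = fit_scaler(np.array([[0.0], [10.0]]))
        assert scaler.transform(np.array([[15.0]]))[0, 0] == 1.5

    def test_constant_column_warns_and_maps_to_zero(self):
        data = np.column_stack([np.arange(5.0), np.full(5, 2.0)])
        with pytest.warns(UserWarning):
            scaler = fit_scaler(data)
        np.testing.assert_allclose(scaler.transform(data)[:, 1], 0.0)


class TestWindowize:
    def test_exact_tiling(self, small_recording):
        sub = small_recording.copy_with(small_recording.channels.copy())
        windows = windowize(sub, 600, 600)
        assert len(windows) == 3

    def test_stride_count_formula(self, small_recording):
        windows = windowize(small_recording, 180, 30)
        assert len(windows) == (len(small_recording) - 180) // 30 + 1

    def test_last_step_labeling_tracks_step(self):
        profile = gen_intermittent(1, seed=6)
        rec = simulate_response(profile, default_array(), drift_on=False)
        windows = windowize(rec, 180, 60)
        for w in windows:
            start = w.origin[1]
            np.testing.assert_allclose(w.target,
                                       rec.truth[start + 179])

    def test_too_long_window_rejected(self, small_recording):
        with pytest.raises(ValueError):
            windowize(small_recording, len(small_recording) + 1, 1)

    def test_save_load_round_trip(self, tmp_path, cycle_windows):
        scaler = fit_scaler(cycle_windows)
        save_windows(cycle_windows[:2], tmp_path / "w", scaler=scaler,
                     stride=600, channel_ids=[f"S{i}" for i in range(1, 24)])
        loaded, loaded_scaler = load_windows(tmp_path / "w")
        assert len(loaded) == 2
        np.testing.assert_allclose(loaded[0].values, cycle_windows[0].values)
        np.testing.assert_allclose(loaded[0].target, cycle_windows[0].target)
        np.testing.assert_allclose(loaded_scaler.col_min, scaler.col_min)


class TestFilterConfig:
    def test_invalid_configs_rejected(self):
        with pytest.raises(ValueError):
            FilterConfig(sg_window=10)
        with pytest.raises(ValueError):
            FilterConfig(sg_window=5, sg_order=5)
        with pytest.raises(ValueError):
            FilterConfig(kalman_q=-1.0)
        with pytest.raises(ValueError):
            FilterConfig(lag_s=-1)
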