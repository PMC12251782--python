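"""Network construction, signal primitives, training and baselines."""

from dataclasses import replace

import numpy as np
import pandas as pd
import pytest

from enosekit.experiments import planted_feature_table
from enosekit.models import (
    BASELINE_NAMES,
    MODEL_NAMES,
    BaselineConfig,
    ConcentrationModel,
    ModelConfig,
    build_model,
    dct_transform,
    decompose_series,
    fit_baseline,
    idct_transform,
    load_checkpoint,
)

TINY = ModelConfig(name="ED-CNN-LSTM", length=24, channels=5,
                   conv_widths=(8, 8, 8), rnn_hidden=8, dct_k=8,
                   attn_reduction=2, decomp_kernel=5, transformer_dim=8,
                   transformer_heads=2, fc_width=16, batch_size=8,
                   epochs=2, seed=0, scale_targets=False)


def tiny_dataset(n=16, seed=0):
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, TINY.length, TINY.channels))
    W = rng.normal(size=(TINY.channels, 8))
    y = X.mean(axis=1) @ W
    return X, y


class TestDCT:
    def test_matches_direct_sum_oracle(self, rng):
        x = rng.normal(size=8)
        L = 8
        direct = np.array([
            sum(x[n] * np.cos(np.pi * (n + 0.5) * k / L) for n in range(L))
            for k in range(L)]) * np.sqrt(2.0 / L)
        direct[0] /= np.sqrt(2.0)
        np.testing.assert_allclose(dct_transform(x), direct, atol=1e-10)

    def test_constant_vector_is_dc_only(self):
        c = dct_transform(np.full(16, 3.0))
        assert abs(c[0]) > 0
        np.testing.assert_allclose(c[1:], 0.0, atol=1e-12)

    def test_round_trip_and_parseval(self, rng):
        x = rng.normal(size=33)
        c = dct_transform(x)
        np.testing.assert_allclose(idct_transform(c), x, atol=1e-10)
        np.testing.assert_allclose((c**2).sum(), (x**2).sum(), rtol=1e-12)

    def test_empty_rejected(self):
        with pytest.raises(ValueError):
            dct_transform(np.array([]))


class TestDecompose:
    def test_constant_window(self):
        w = np.full((30, 4), 2.0)
        trend, seasonal = decompose_series(w, 5)
        np.testing.assert_allclose(trend, w)
        np.testing.assert_allclose(seasonal, 0.0)

    def test_exact_reconstruction(self, rng):
        w = rng.normal(size=(40, 3))
        trend, seasonal = decompose_series(w, 7)
        np.testing.assert_allclose(trend + seasonal, w, atol=1e-12)

    def test_linear_ramp_interior(self):
        ramp = np.arange(50.0)[:, None]
        trend, _ = decompose_series(ramp, 5)
        np.testing.assert_allclose(trend[2:-2], ramp[2:-2], atol=1e-10)

    def test_even_kernel_rejected(self):
        with pytest.raises(ValueError):
            decompose_series(np.zeros((10, 2)), 4)


class TestBuildModel:
    @pytest.mark.parametrize("name", MODEL_NAMES)
    def test_forward_shape_is_batch_by_8(self, name, rng):
        model = build_model(replace(TINY, name=name))
        out = model.forward_array(rng.normal(size=(3, TINY.length,
                                                   TINY.channels)))
        assert out.shape == (3, 8)

    def test_parameter_counts_increase_along_ablations(self):
        counts = [build_model(replace(TINY, name=n)).n_parameters()
                  for n in ("ED-CNN-LSTM", "ED-CNN-DCT-LSTM",
                            "IED-CNN-LSTM")]
        assert counts[0] < counts[1] < counts[2]

    def test_zeroed_compensation_equals_dct_ablation(self, rng):
        ied = build_model(replace(TINY, name="IED-CNN-LSTM", seed=3))
        ed = build_model(replace(TINY, name="ED-CNN-DCT-LSTM", seed=3))
        comp_ids = {id(p) for p in ied.comp.parameters()}
        main = [p for p in ied.parameters() if id(p) not in comp_ids]
        for a, b in zip(main, ed.parameters()):
            a.data = b.data.copy()
        for p in ied.comp.parameters():
            p.data[...] = 0.0
        x = rng.normal(size=(2, TINY.length, TINY.channels))
        np.testing.assert_array_equal(ied.forward_array(x).data,
                                      ed.forward_array(x).data)

    def test_unknown_name_rejected(self):
        with pytest.raises(ValueError):
            ModelConfig(name="GRU")


class TestTraining:
    def test_same_seed_identical_weights_and_predictions(self):
        X, y = tiny_dataset()
        a = ConcentrationModel(X, y, TINY).fit()
        b = ConcentrationModel(X, y, TINY).fit()
        for pa, pb in zip(a.network.parameters(), b.network.parameters()):
            np.testing.assert_array_equal(pa.data, pb.data)
        np.testing.assert_array_equal(a.predict(X), b.predict(X))

    def test_capacity_overfits_small_set(self):
        # a handful of windows should be memorized almost exactly
        X, y = tiny_dataset(n=16)
        cfg = replace(TINY, epochs=200, lr=3e-3)
        res = ConcentrationModel(X, y, cfg).fit()
        rmse = float(np.sqrt(np.mean((res.predict(X) - y) ** 2)))
        target_range = y.max() - y.min()
        assert rmse < 0.05 * target_range
        # loss history sane: finite, and smoothed trend nonincreasing
        hist = np.asarray(res.loss_history)
        assert np.isfinite(hist).all()
        smooth = np.convolve(hist, np.ones(10) / 10, mode="valid")
        assert smooth[-1] <= smooth[0]

    def test_summary_reports_fit(self):
        X, y = tiny_dataset()
        res = ConcentrationModel(X, y, TINY).fit()
        text = res.summary(X, y)
        assert "ED-CNN-LSTM" in text and "RMSE" in text

    def test_checkpoint_round_trip(self, tmp_path):
        X, y = tiny_dataset()
        res = ConcentrationModel(X, y, TINY).fit()
        res.save(tmp_path / "ck")
        loaded = load_checkpoint(tmp_path / "ck")
        np.testing.assert_array_equal(loaded.predict(X), res.predict(X))

    def test_shape_mismatch_rejected(self):
        X, y = tiny_dataset()
        with pytest.raises(ValueError):
            ConcentrationModel(X[:, :, :3], y, TINY)


@pytest.fixture(scope="module")
def planted_split():
    table, _ = planted_feature_table(seed=7, n_samples=200)
    return table.iloc[:160], table.iloc[160:]


class TestBaselines:
    def test_knn_exact_at_training_point(self, planted_split):
        train, _ = planted_split
        est = fit_baseline(BaselineConfig(name="KNN"), train)
        feat_cols = [c for c in train.columns if not c.startswith("y_")]
        y_cols = [c for c in train.columns if c.startswith("y_")]
        pred = est.predict(train[feat_cols].to_numpy()[:3])
        np.testing.assert_allclose(pred, train[y_cols].to_numpy()[:3],
                                   atol=1e-5)

    def test_rf_seed_42_reproducible(self, planted_split):
        train, test = planted_split
        feat_cols = [c for c in train.columns if not c.startswith("y_")]
        cfg = BaselineConfig(name="RF", rf_estimators=50)
        p1 = fit_baseline(cfg, train).predict(test[feat_cols].to_numpy())
        p2 = fit_baseline(cfg, train).predict(test[feat_cols].to_numpy())
        np.testing.assert_array_equal(p1, p2)

    @pytest.mark.parametrize("name", BASELINE_NAMES)
    def test_planted_signal_learnable_by_every_baseline(self, name,
                                                        planted_split):
        train, test = planted_split
        feat_cols = [c for c in train.columns if not c.startswith("y_")]
        cfg = BaselineConfig(name=name, rf_estimators=100,
                             xgb_estimators=150)
        est = fit_baseline(cfg, train)
        pred = est.predict(test[feat_cols].to_numpy())
        truth = test[[c for c in test.columns
                      if c.startswith("y_")]].to_numpy()
        # informative only for gas 1: judge R^2 on that output
        ss_res = np.sum((pred[:, 0] - truth[:, 0]) ** 2)
        ss_tot = np.sum((truth[:, 0] - truth[:, 0].mean()) ** 2)
        assert 1 - ss_res / ss_tot > 0.0

    def test_unknown_baseline_rejected(self):
        with pytest.raises(ValueError):
            BaselineConfig(name="GBM")
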