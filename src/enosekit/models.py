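"""Concentration models: the encoder-decoder CNN/LSTM family and the
classical feature-based baselines.

The flagship network couples an Encoder-Decoder main structure with an
external drift-compensation branch:

* **Encoder** — a three-layer 1-D CNN block (with a normalization layer)
  in parallel with a two-layer bidirectional LSTM block, fused by
  feature-axis concatenation and a linear projection;
* **DCT attention** — frequency-domain channel gating applied to the fused
  encoding;
* **Decoder** — a two-layer unidirectional LSTM followed by fully connected
  layers producing the 8-gas concentration vector;
* **Compensation branch** — the input window is decomposed into trend and
  seasonal parts (centered moving average); the trend passes through an MLP
  and the seasonal part through a transformer encoder layer, the two are
  fused, gated by DCT attention, flattened and mapped to an additive
  8-vector correction.

Ablations drop components: ``ED-CNN-LSTM`` has neither attention nor
compensation, ``ED-CNN-DCT-LSTM`` adds the attention, ``IED-CNN-LSTM`` adds
the compensation branch.  Simpler baselines (CNN, LSTM, BiLSTM and their
serial hybrids) share the same blocks and hidden sizes for fairness.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.fft import dct as _dct, idct as _idct
from scipy.ndimage import uniform_filter1d
from sklearn.ensemble import RandomForestRegressor
from sklearn.multioutput import MultiOutputRegressor
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVR
from xgboost import XGBRegressor

from . import nn
from .nn import Tensor

__all__ = [
    "MODEL_NAMES", "BASELINE_NAMES", "ModelConfig", "BaselineConfig",
    "dct_transform", "idct_transform", "decompose_series",
    "build_model", "train_model", "fit_baseline",
    "ConcentrationModel", "ConcentrationResults",
    "save_checkpoint", "load_checkpoint",
]

#: benchmark roster, weakest to strongest
MODEL_NAMES = ("CNN", "LSTM", "BiLSTM", "CNN-LSTM", "CNN-BiLSTM",
               "ED-CNN-LSTM", "ED-CNN-DCT-LSTM", "IED-CNN-LSTM")
BASELINE_NAMES = ("KNN", "SVM", "RF", "XGBoost", "MLP")


# --------------------------------------------------------------------------
# small signal primitives
# --------------------------------------------------------------------------

def dct_transform(x: np.ndarray) -> np.ndarray:
    """Orthonormal DCT-II along the last axis (Parseval-preserving)."""
    x = np.asarray(x, dtype=float)
    if x.size == 0:
        raise ValueError("empty input")
    return _dct(x, type=2, norm="ortho", axis=-1)


def idct_transform(c: np.ndarray) -> np.ndarray:
    """Inverse of :func:`dct_transform` (orthonormal DCT-III)."""
    c = np.asarray(c, dtype=float)
    if c.size == 0:
        raise ValueError("empty input")
    return _idct(c, type=2, norm="ortho", axis=-1)


def decompose_series(window: np.ndarray, kernel: int
                     ) -> tuple[np.ndarray, np.ndarray]:
    """Split a window into (trend, seasonal) parts along the time axis.

    Trend is a centered moving average of odd width ``kernel`` with edge
    replication; seasonal is the residual, so trend + seasonal reconstructs
    the input exactly.  Accepts (L, C) or (B, L, C).
    """
    if kernel % 2 == 0:
        raise ValueError("kernel must be odd")
    x = np.asarray(window, dtype=float)
    axis = 0 if x.ndim == 2 else 1
    if kernel > x.shape[axis]:
        raise ValueError("kernel exceeds the window length")
    trend = uniform_filter1d(x, size=kernel, axis=axis, mode="nearest")
    return trend, x - trend


# --------------------------------------------------------------------------
# configuration
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    name: str = "IED-CNN-LSTM"
    length: int = 180
    channels: int = 18
    conv_widths: tuple[int, int, int] = (32, 64, 64)
    conv_kernel: int = 3
    rnn_hidden: int = 64
    dct_k: int = 16
    attn_reduction: int = 4
    decomp_kernel: int = 25
    transformer_dim: int = 32
    transformer_heads: int = 4
    transformer_layers: int = 1
    fc_width: int = 64
    loss: str = "mse"
    optimizer: str = "adam"
    lr: float = 1e-3
    weight_decay: float = 0.0
    batch_size: int = 32
    epochs: int = 100
    comp_epochs: int | None = None  # compensation stage length; None = epochs // 2
    seed: int = 0
    comp_channels: tuple[int, ...] | None = None  # None = all input channels
    scale_targets: bool = True  # train in min-max-normalized target space

    def __post_init__(self):
        if self.name not in MODEL_NAMES:
            raise ValueError(f"unknown model name {self.name!r}")
        if self.decomp_kernel % 2 == 0:
            raise ValueError("decomp_kernel must be odd")
        if self.dct_k > self.length:
            raise ValueError("dct_k must not exceed the window length")


@dataclass(frozen=True)
class BaselineConfig:
    """Classical regressors with their tuned hyperparameters as defaults."""

    name: str = "KNN"
    knn_k: int = 4
    knn_weights: str = "distance"
    svm_c: float = 50.0
    svm_kernel: str = "rbf"
    rf_estimators: int = 700
    rf_depth: int = 9
    rf_seed: int = 42
    xgb_estimators: int = 850
    xgb_lr: float = 0.025
    xgb_depth: int = 4
    xgb_penalty: float = 0.026
    mlp_hidden: tuple[int, int] = (300, 150)
    mlp_lr: float = 4e-4
    mlp_iters: int = 100

    def __post_init__(self):
        if self.name not in BASELINE_NAMES:
            raise ValueError(f"unknown baseline name {self.name!r}")


# --------------------------------------------------------------------------
# network definitions
# --------------------------------------------------------------------------

class CNNBlock(nn.Module):
    """Three same-padded 1-D convolutions with ReLU, then layer norm."""

    def __init__(self, in_ch: int, widths: tuple[int, int, int], kernel: int,
                 rng: np.random.Generator):
        w1, w2, w3 = widths
        self.c1 = nn.Conv1d(in_ch, w1, kernel, rng)
        self.c2 = nn.Conv1d(w1, w2, kernel, rng)
        self.c3 = nn.Conv1d(w2, w3, kernel, rng)
        self.norm = nn.LayerNorm(w3)

    def forward(self, x: Tensor) -> Tensor:
        h = nn.relu(self.c1(x))
        h = nn.relu(self.c2(h))
        h = nn.relu(self.c3(h))
        return self.norm(h)


class _SeqNet(nn.Module):
    """Shared skeleton: every model maps a (B, L, C) array to (B, 8)."""

    def forward_array(self, x: np.ndarray) -> Tensor:
        return self.forward(Tensor(np.asarray(x, dtype=float)))


class CNNModel(_SeqNet):
    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        self.cnn = CNNBlock(cfg.channels, cfg.conv_widths, cfg.conv_kernel, rng)
        self.head = nn.MLP([cfg.length * cfg.conv_widths[2], cfg.fc_width, 8],
                           rng)

    def forward(self, x: Tensor) -> Tensor:
        h = self.cnn(x)
        B, L, C = h.shape
        return self.head(h.reshape(B, L * C))


class RNNModel(_SeqNet):
    """Two stacked recurrent layers (uni- or bidirectional) + FC head."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 bidirectional: bool, in_dim: int | None = None,
                 cnn_front: bool = False):
        H = cfg.rnn_hidden
        self.cnn = (CNNBlock(cfg.channels, cfg.conv_widths, cfg.conv_kernel,
                             rng) if cnn_front else None)
        d = cfg.conv_widths[2] if cnn_front else (in_dim or cfg.channels)
        if bidirectional:
            self.r1 = nn.BiLSTM(d, H, rng)
            self.r2 = nn.BiLSTM(2 * H, H, rng)
            out_dim = 2 * H
        else:
            self.r1 = nn.LSTM(d, H, rng)
            self.r2 = nn.LSTM(H, H, rng)
            out_dim = H
        self.head = nn.MLP([out_dim, cfg.fc_width, 8], rng)

    def forward(self, x: Tensor) -> Tensor:
        if self.cnn is not None:
            x = self.cnn(x)
        h = self.r2(self.r1(x))
        return self.head(h[:, -1, :])


class CompensationBranch(nn.Module):
    """Trend/seasonal decomposition -> MLP + transformer -> additive 8-vector."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator):
        C = (len(cfg.comp_channels) if cfg.comp_channels is not None
             else cfg.channels)
        d = cfg.transformer_dim
        self.cfg = cfg
        self.trend_mlp = nn.MLP([C, d, d], rng)
        self.seasonal_embed = nn.Linear(C, d, rng)
        self.seasonal_layers = [
            nn.TransformerEncoderLayer(d, cfg.transformer_heads, 2 * d, rng)
            for _ in range(cfg.transformer_layers)
        ]
        self.attn = nn.DCTAttention(2 * d, cfg.length, cfg.dct_k,
                                    cfg.attn_reduction, rng)
        self.head = nn.MLP([cfg.length * 2 * d, cfg.fc_width, 8], rng)
        # zero-init the output layer: the additive correction starts at 0,
        # so the full model begins exactly at its no-compensation ablation
        self.head.layers[-1].weight.data[...] = 0.0
        self.head.layers[-1].bias.data[...] = 0.0

    def forward_array(self, x: np.ndarray) -> Tensor:
        cfg = self.cfg
        if cfg.comp_channels is not None:
            x = x[:, :, list(cfg.comp_channels)]
        trend, seasonal = decompose_series(x, cfg.decomp_kernel)
        t = self.trend_mlp(Tensor(trend))
        s = self.seasonal_embed(Tensor(seasonal))
        for layer in self.seasonal_layers:
            s = layer(s)
        fused = nn.concatenate([t, s], axis=-1)
        gated = self.attn(fused)
        B, L, D = gated.shape
        return self.head(gated.reshape(B, L * D))


class EncoderDecoder(_SeqNet):
    """ED-CNN-LSTM and its DCT-attention / compensation extensions."""

    def __init__(self, cfg: ModelConfig, rng: np.random.Generator,
                 use_attention: bool, use_compensation: bool):
        H = cfg.rnn_hidden
        self.cfg = cfg
        self.cnn = CNNBlock(cfg.channels, cfg.conv_widths, cfg.conv_kernel, rng)
        self.bi1 = nn.BiLSTM(cfg.channels, H, rng)
        self.bi2 = nn.BiLSTM(2 * H, H, rng)
        self.fuse = nn.Linear(cfg.conv_widths[2] + 2 * H, 2 * H, rng)
        self.attn = (nn.DCTAttention(2 * H, cfg.length, cfg.dct_k,
                                     cfg.attn_reduction, rng)
                     if use_attention else None)
        self.dec1 = nn.LSTM(2 * H, H, rng)
        self.dec2 = nn.LSTM(H, H, rng)
        self.head = nn.MLP([H, cfg.fc_width, 8], rng)
        self.comp = CompensationBranch(cfg, rng) if use_compensation else None

    def forward(self, x: Tensor) -> Tensor:
        conv = self.cnn(x)
        rec = self.bi2(self.bi1(x))
        fused = self.fuse(nn.concatenate([conv, rec], axis=-1))
        if self.attn is not None:
            fused = self.attn(fused)
        h = self.dec2(self.dec1(fused))[:, -1, :]
        return self.head(h)

    def forward_array(self, x: np.ndarray) -> Tensor:
        x = np.asarray(x, dtype=float)
        main = self.forward(Tensor(x))
        if self.comp is None:
            return main
        return main + self.comp.forward_array(x)


def build_model(config: ModelConfig) -> _SeqNet:
    """Instantiate a network from its config (weights seeded by config.seed)."""
    rng = np.random.default_rng(config.seed)
    name = config.name
    if name == "CNN":
        return CNNModel(config, rng)
    if name == "LSTM":
        return RNNModel(config, rng, bidirectional=False)
    if name == "BiLSTM":
        return RNNModel(config, rng, bidirectional=True)
    if name == "CNN-LSTM":
        return RNNModel(config, rng, bidirectional=False, cnn_front=True)
    if name == "CNN-BiLSTM":
        return RNNModel(config, rng, bidirectional=True, cnn_front=True)
    if name == "ED-CNN-LSTM":
        return EncoderDecoder(config, rng, False, False)
    if name == "ED-CNN-DCT-LSTM":
        return EncoderDecoder(config, rng, True, False)
    if name == "IED-CNN-LSTM":
        return EncoderDecoder(config, rng, True, True)
    raise ValueError(f"unknown model name {name!r}")


# --------------------------------------------------------------------------
# training
# --------------------------------------------------------------------------

def _run_epochs(model, X, y, params, opt, epochs, batch_size, rng, verbose,
                tag=""):
    history: list[float] = []
    all_params = model.parameters()
    n = len(X)
    bs = min(batch_size, n)
    for epoch in range(epochs):
        order = rng.permutation(n)
        epoch_loss, seen = 0.0, 0
        for lo in range(0, n, bs):
            idx = order[lo : lo + bs]
            pred = model.forward_array(X[idx])
            loss = ((pred - Tensor(y[idx])) ** 2).mean()
            value = float(loss.data)
            if not np.isfinite(value):
                raise RuntimeError(
                    f"non-finite loss at epoch {epoch}, batch {lo // bs}: "
                    f"{value}")
            for p in all_params:
                p.grad = None
            loss.backward()
            opt.step()
            epoch_loss += value * len(idx)
            seen += len(idx)
        history.append(epoch_loss / seen)
        if verbose:
            print(f"{tag}epoch {epoch + 1:3d}/{epochs}  "
                  f"loss {history[-1]:.5f}")
    return history


def train_model(model: _SeqNet, X: np.ndarray, y: np.ndarray,
                config: ModelConfig, verbose: bool = False) -> list[float]:
    """Minimize MSE with Adam over shuffled mini-batches; returns loss history.

    Models with a compensation branch train in two stages: the main
    encoder-decoder first (the zero-initialized branch contributes nothing),
    then the branch alone on the full-model loss, so the external correction
    fits the main model's residual error rather than competing with it.
    Deterministic for a fixed config.seed under single-threaded BLAS.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 3 or y.ndim != 2 or len(X) != len(y):
        raise ValueError("X must be (n, L, C) and y (n, 8)")
    rng = np.random.default_rng(config.seed + 1)
    comp = getattr(model, "comp", None)
    if comp is None:
        opt = nn.Adam(model.parameters(), lr=config.lr,
                      weight_decay=config.weight_decay)
        return _run_epochs(model, X, y, model.parameters(), opt,
                           config.epochs, config.batch_size, rng, verbose)
    comp_ids = {id(p) for p in comp.parameters()}
    main_params = [p for p in model.parameters() if id(p) not in comp_ids]
    opt_main = nn.Adam(main_params, lr=config.lr,
                       weight_decay=config.weight_decay)
    history = _run_epochs(model, X, y, main_params, opt_main, config.epochs,
                          config.batch_size, rng, verbose, tag="main ")
    comp_epochs = (config.comp_epochs if config.comp_epochs is not None
                   else max(config.epochs // 2, 1))
    opt_comp = nn.Adam(comp.parameters(), lr=config.lr,
                       weight_decay=config.weight_decay)
    history += _run_epochs(model, X, y, comp.parameters(), opt_comp,
                           comp_epochs, config.batch_size, rng, verbose,
                           tag="comp ")
    return history


def predict_model(model: _SeqNet, X: np.ndarray,
                  batch_size: int = 256) -> np.ndarray:
    X = np.asarray(X, dtype=float)
    outs = [model.forward_array(X[lo : lo + batch_size]).data
            for lo in range(0, len(X), batch_size)]
    return np.concatenate(outs, axis=0)


# --------------------------------------------------------------------------
# classical baselines
# --------------------------------------------------------------------------

def fit_baseline(config: BaselineConfig, table: pd.DataFrame):
    """Fit a classical multi-output regressor on a feature table.

    Returns an object with a ``predict(X)`` method; feature columns are all
    non-``y_`` columns in table order.
    """
    feat_cols = [c for c in table.columns if not c.startswith("y_")]
    y_cols = [c for c in table.columns if c.startswith("y_")]
    X = table[feat_cols].to_numpy(float)
    Y = table[y_cols].to_numpy(float)
    name = config.name
    if name == "KNN":
        est = KNeighborsRegressor(n_neighbors=config.knn_k,
                                  weights=config.knn_weights)
    elif name == "SVM":
        est = MultiOutputRegressor(make_pipeline(
            StandardScaler(), SVR(kernel=config.svm_kernel, C=config.svm_c)))
    elif name == "RF":
        est = RandomForestRegressor(n_estimators=config.rf_estimators,
                                    max_depth=config.rf_depth,
                                    random_state=config.rf_seed, n_jobs=1)
    elif name == "XGBoost":
        est = XGBRegressor(n_estimators=config.xgb_estimators,
                           learning_rate=config.xgb_lr,
                           max_depth=config.xgb_depth,
                           reg_lambda=config.xgb_penalty,
                           random_state=0, n_jobs=1,
                           tree_method="hist")
    elif name == "MLP":
        est = make_pipeline(
            StandardScaler(),
            MLPRegressor(hidden_layer_sizes=config.mlp_hidden,
                         learning_rate_init=config.mlp_lr,
                         max_iter=config.mlp_iters, solver="adam",
                         random_state=0))
    else:
        raise ValueError(f"unknown baseline name {name!r}")
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # MLP convergence at 100 iters
        est.fit(X, Y)
    return est


# --------------------------------------------------------------------------
# Model / Results interface
# --------------------------------------------------------------------------

class ConcentrationModel:
    """A concentration regression problem: windows, targets and a config.

    ``fit()`` trains the configured network and returns a
    :class:`ConcentrationResults` carrying the trained weights, the loss
    history and evaluation helpers.
    """

    def __init__(self, X: np.ndarray, y: np.ndarray,
                 config: ModelConfig | None = None):
        self.X = np.asarray(X, dtype=float)
        self.y = np.asarray(y, dtype=float)
        if config is None:
            config = ModelConfig(length=self.X.shape[1],
                                 channels=self.X.shape[2])
        if config.length != self.X.shape[1] or config.channels != self.X.shape[2]:
            raise ValueError("config length/channels do not match the data")
        self.config = config

    @classmethod
    def from_windows(cls, windows, config: ModelConfig | None = None,
                     scaler=None) -> "ConcentrationModel":
        X = np.stack([w.values for w in windows])
        if scaler is not None:
            X = scaler.transform(X)
        y = np.stack([w.target for w in windows])
        return cls(X, y, config)

    def fit(self, verbose: bool = False) -> "ConcentrationResults":
        network = build_model(self.config)
        y = self.y
        target_scale = None
        if self.config.scale_targets:
            # min-max normalize targets for well-conditioned optimization;
            # predictions are mapped back to ppm
            lo = y.min(axis=0)
            span = y.max(axis=0) - lo
            span = np.where(span == 0.0, 1.0, span)
            target_scale = (lo, span)
            y = (y - lo) / span
        history = train_model(network, self.X, y, self.config,
                              verbose=verbose)
        return ConcentrationResults(self.config, network, history,
                                    target_scale)


class ConcentrationResults:
    """Fitted model: weights, loss history, prediction and reporting."""

    def __init__(self, config: ModelConfig, network: _SeqNet,
                 loss_history: list[float],
                 target_scale: tuple[np.ndarray, np.ndarray] | None = None):
        self.config = config
        self.network = network
        self.loss_history = list(loss_history)
        self.target_scale = target_scale

    def predict(self, X: np.ndarray) -> np.ndarray:
        out = predict_model(self.network, X)
        if self.target_scale is not None:
            lo, span = self.target_scale
            out = out * span + lo
        return out

    def evaluate(self, X: np.ndarray, y: np.ndarray):
        from .evaluate import compute_metrics

        return compute_metrics(np.asarray(y, float), self.predict(X))

    @property
    def n_parameters(self) -> int:
        return self.network.n_parameters()

    def summary(self, X: np.ndarray | None = None,
                y: np.ndarray | None = None) -> str:
        lines = [
            f"{self.config.name} concentration model",
            "=" * 44,
            f"window length        {self.config.length}",
            f"input channels       {self.config.channels}",
            f"parameters           {self.n_parameters}",
            f"epochs               {len(self.loss_history)}",
            f"final train MSE      {self.loss_history[-1]:.5f}",
        ]
        if X is not None and y is not None:
            rep = self.evaluate(X, y)
            lines += [
                f"eval RMSE (ppm)      {rep.pooled.rmse:.3f}",
                f"eval R^2             {rep.pooled.r2:.3f}",
                f"eval CORR            {rep.pooled.corr:.3f}",
            ]
        return "\n".join(lines)

    def save(self, path) -> None:
        save_checkpoint(self, path)


def save_checkpoint(results: ConcentrationResults, path) -> None:
    """Persist config + weights + loss history as an .npz alongside JSON."""
    path = Path(path)
    arrays = results.network.state_arrays()
    np.savez(path.with_suffix(".npz"),
             **{f"w{i}": a for i, a in enumerate(arrays)})
    meta = {"config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in results.config.__dict__.items()},
            "loss_history": results.loss_history,
            "target_scale": ([results.target_scale[0].tolist(),
                              results.target_scale[1].tolist()]
                             if results.target_scale is not None else None),
            "n_arrays": len(arrays)}
    path.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def load_checkpoint(path) -> ConcentrationResults:
    path = Path(path)
    meta = json.loads(path.with_suffix(".json").read_text())
    cfg_dict = meta["config"]
    for key in ("conv_widths", "mlp_hidden", "comp_channels"):
        if key in cfg_dict and isinstance(cfg_dict[key], list):
            cfg_dict[key] = tuple(cfg_dict[key])
    config = ModelConfig(**cfg_dict)
    network = build_model(config)
    with np.load(path.with_suffix(".npz")) as data:
        arrays = [data[f"w{i}"] for i in range(meta["n_arrays"])]
    network.load_state_arrays(arrays)
    ts = meta.get("target_scale")
    target_scale = ((np.asarray(ts[0]), np.asarray(ts[1]))
                    if ts is not None else None)
    return ConcentrationResults(config, network, meta["loss_history"],
                                target_scale)
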