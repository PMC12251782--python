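"""Reproducible scaled-down study recipes.

These functions wire the full pipeline — exposure generation, sensor
simulation, filtering, windowing, scaling, training, evaluation — into
fixed synthetic experiments sized for a single CPU.  They are the package's
reference experiments; the acceptance script and the benchmark command both
run them.

All problem sizes here are deliberate scale reductions of the full
protocol (thousands of cycles, 180-s windows) chosen so each experiment
trains in minutes; see docs/methods.md for the rationale.
"""

from __future__ import annotations

from dataclasses import replace

import numpy as np
import pandas as pd

from .evaluate import compute_metrics, run_benchmark, split_dataset
from .features import FEATURE_NAMES, extract_features, feature_channel_map
from .models import ModelConfig
from .preprocess import FilterConfig, SampleWindow, fit_scaler, \
    preprocess_recording, windowize
from .select import build_rank_matrix
from .simulate import ExposureProfile, GAS_NAMES, default_array, \
    gen_continuous, gen_intermittent, simulate_response

__all__ = [
    "continuous_dataset",
    "scaled_model_config",
    "model_recovery",
    "compensation_ordering",
    "filtering_gain",
    "planted_feature_table",
    "selection_recovery",
    "drift_pulse_amplitudes",
]


#: lag hyperparameter for the default array: about one EC response constant,
#: found by cross-correlating simulated responses with the true input
DEFAULT_LAG_S = 25


def continuous_dataset(seed: int, n_conditions: int = 60, drift: bool = False,
                       window: int = 120, stride: int = 30,
                       filter_config: FilterConfig | None = None):
    """Simulate, filter, window, split and scale a continuous-protocol run.

    Returns ``(X_train, y_train, X_test, y_test, scaler)`` with X scaled to
    the training minima/maxima per channel.
    """
    profile = gen_continuous(n_conditions, seed=seed)
    rec = simulate_response(profile, default_array(), seed=seed + 1,
                            drift_on=drift)
    rec = preprocess_recording(
        rec, filter_config or FilterConfig(lag_s=DEFAULT_LAG_S))
    windows = windowize(rec, window, stride, recording_id=f"cont{seed}")
    train_w, test_w = split_dataset(windows, ratio=0.8, seed=seed + 2)
    scaler = fit_scaler(train_w)
    X_tr = scaler.transform(np.stack([w.values for w in train_w]))
    X_te = scaler.transform(np.stack([w.values for w in test_w]))
    y_tr = np.stack([w.target for w in train_w])
    y_te = np.stack([w.target for w in test_w])
    return X_tr, y_tr, X_te, y_te, scaler


def scaled_model_config(length: int, channels: int, **overrides) -> ModelConfig:
    """The reduced-size network shared by the synthetic experiments."""
    base = ModelConfig(
        name="ED-CNN-LSTM", length=length, channels=channels,
        conv_widths=(16, 32, 32), rnn_hidden=32, dct_k=16, attn_reduction=4,
        decomp_kernel=25, transformer_dim=16, transformer_heads=4,
        fc_width=64, lr=1e-3, batch_size=32, epochs=30, seed=0)
    return replace(base, **overrides)


def model_recovery(seed: int = 0, n_conditions: int = 60,
                   verbose: bool = False) -> dict:
    """Drift-free learnability: train the reduced ED-CNN-LSTM and report
    held-out pooled metrics."""
    from .models import ConcentrationModel

    X_tr, y_tr, X_te, y_te, _ = continuous_dataset(
        seed, n_conditions=n_conditions, drift=False, window=120, stride=30)
    cfg = scaled_model_config(X_tr.shape[1], X_tr.shape[2],
                              name="ED-CNN-LSTM", epochs=30, seed=seed)
    res = ConcentrationModel(X_tr, y_tr, cfg).fit(verbose=verbose)
    rep = res.evaluate(X_te, y_te)
    return {"r2": rep.pooled.r2, "rmse": rep.pooled.rmse,
            "corr": rep.pooled.corr, "n_train": len(X_tr),
            "n_test": len(X_te), "results": res,
            "test": (X_te, y_te)}


ORDERING_MODELS = ("ED-CNN-LSTM", "ED-CNN-DCT-LSTM", "IED-CNN-LSTM")


def compensation_ordering(seeds=(0, 1, 2), n_conditions: int = 40,
                          verbose: bool = False) -> dict:
    """Drift-on ablation: per-seed test RMSE for the encoder-decoder family.

    Returns the benchmark table plus the median test RMSE per model over
    seeds, in roster order (expected nonincreasing toward IED-CNN-LSTM).
    """
    frames = []
    for seed in seeds:
        X_tr, y_tr, X_te, y_te, _ = continuous_dataset(
            100 + seed, n_conditions=n_conditions, drift=True,
            window=90, stride=30)
        cfg = scaled_model_config(X_tr.shape[1], X_tr.shape[2],
                                  epochs=10, comp_epochs=5, lr=2e-3,
                                  weight_decay=1e-3, transformer_dim=8,
                                  transformer_heads=2)
        df = run_benchmark(ORDERING_MODELS, (X_tr, y_tr), (X_te, y_te),
                           cfg, seeds=(seed,), verbose=verbose)
        frames.append(df)
    table = pd.concat(frames, ignore_index=True)
    test = table[table["split"] == "test"]
    medians = {m: float(test[test["model"] == m]["RMSE"].median())
               for m in ORDERING_MODELS}
    return {"table": table, "median_test_rmse": medians}


def filtering_gain(n_seeds: int = 20, n_cycles: int = 2,
                   filter_config: FilterConfig | None = None) -> dict:
    """Paired filtering test: does Kalman->SG reduce MSE to the clean twin?

    For each seed a noisy recording and its noise/drift-free twin share one
    exposure profile; the win count is the number of seeds where filtering
    strictly reduces the mean squared deviation from the twin.
    """
    fc = filter_config or FilterConfig()
    quiet = default_array({"*": {"noise_sd": 0.0, "drift_walk_sd": 0.0,
                                 "carryover": 0.0}})
    noisy_specs = default_array()
    wins = 0
    ratios = []
    for seed in range(n_seeds):
        profile = gen_intermittent(n_cycles, seed=seed)
        clean = simulate_response(profile, quiet, seed=seed, drift_on=False)
        noisy = simulate_response(profile, noisy_specs, seed=seed,
                                  drift_on=False)
        filtered = preprocess_recording(noisy, fc)
        mse_raw = float(np.mean((noisy.channels - clean.channels) ** 2))
        mse_filt = float(np.mean((filtered.channels - clean.channels) ** 2))
        ratios.append(mse_filt / mse_raw)
        wins += mse_filt < mse_raw
    return {"wins": wins, "n_seeds": n_seeds,
            "mean_mse_ratio": float(np.mean(ratios))}


def planted_feature_table(seed: int, n_samples: int = 150,
                          n_sensors: int = 6,
                          informative: str = "S3") -> tuple[pd.DataFrame, dict]:
    """Synthetic feature table where exactly one sensor carries the signal.

    The informative sensor's nine features are noisy affine images of the
    first gas concentration; every other feature is independent noise.
    Returns the table and the feature->sensor channel map.
    """
    rng = np.random.default_rng(seed)
    sensors = [f"S{i + 1}" for i in range(n_sensors)]
    if informative not in sensors:
        raise ValueError(f"{informative} not among {sensors}")
    y = rng.uniform(0.0, 14.0, size=(n_samples, len(GAS_NAMES)))
    cols = {}
    for cid in sensors:
        for k, feat in enumerate(FEATURE_NAMES):
            if cid == informative:
                slope = rng.uniform(0.5, 2.0)
                vals = slope * y[:, 0] + rng.normal(0, 1.0, n_samples)
            else:
                vals = rng.normal(0, 5.0, n_samples)
            cols[f"{cid}:{feat}"] = vals
    table = pd.DataFrame(cols)
    for j, g in enumerate(GAS_NAMES):
        table[f"y_{g}"] = y[:, j]
    return table, feature_channel_map(sensors)


def selection_recovery(n_seeds: int = 20) -> dict:
    """How often the ensemble Sensor_Rank puts the planted sensor first."""
    hits = 0
    for seed in range(n_seeds):
        table, cmap = planted_feature_table(seed)
        rm = build_rank_matrix(table, cmap, seed=seed)
        best = min(rm.sensor, key=lambda c: (rm.sensor[c], c))
        hits += best == "S3"
    return {"hits": hits, "n_seeds": n_seeds, "rate": hits / n_seeds}


def _two_pulse_profile(conc_ppm: float = 10.0, gas_index: int = 0,
                       pre: int = 300, pulse: int = 180, gap: int = 120,
                       tail: int = 300) -> ExposureProfile:
    T = pre + pulse + gap + pulse + tail
    conc = np.zeros((T, len(GAS_NAMES)))
    p1 = (pre, pre + pulse)
    p2 = (pre + pulse + gap, pre + 2 * pulse + gap)
    conc[p1[0]:p1[1], gas_index] = conc_ppm
    conc[p2[0]:p2[1], gas_index] = conc_ppm
    segments = [(0, p1[0], "clean"), (p1[0], p1[1], "gas"),
                (p1[1], p2[0], "clean"), (p2[0], p2[1], "gas"),
                (p2[1], T, "clean")]
    return ExposureProfile(
        np.arange(T, dtype=float), conc, np.full(T, 25.0), np.full(T, 57.0),
        np.full(T, 101.3), segments)


def drift_pulse_amplitudes(seed: int = 0, channel: str = "S4",
                           conc_ppm: float = 10.0) -> dict:
    """Response amplitude of two identical pulses with a short clean gap.

    The gap (120 s) is shorter than five recovery time constants of the EC
    channel, so with drift enabled the carried-over excess and the baseline
    walk shift the second pulse.  Each amplitude is the pulse-end plateau
    mean relative to the initial clean-air level; plateau averaging (40 s)
    suppresses measurement noise, and referencing both pulses to the same
    clean level isolates drift from ordinary incomplete recovery.
    """
    profile = _two_pulse_profile(conc_ppm=conc_ppm, gas_index=1)
    sensors = default_array()
    idx = [s.id for s in sensors].index(channel)
    out = {}
    for drift_on in (False, True):
        rec = simulate_response(profile, sensors, seed=seed, drift_on=drift_on)
        ch = rec.channels[:, idx]
        gas_segments = [s for s in profile.segments if s[2] == "gas"]
        clean_level = ch[gas_segments[0][0] - 40 : gas_segments[0][0]].mean()
        amp = [float(ch[end - 40 : end].mean() - clean_level)
               for start, end, _ in gas_segments]
        out["drift_on" if drift_on else "drift_off"] = amp
    noise_sd = [s for s in sensors if s.id == channel][0].noise_sd
    # 3 sigma for a difference of two 40-sample plateau means
    out["noise_floor"] = float(3.0 * noise_sd * np.sqrt(2.0 / 40.0))
    return out
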