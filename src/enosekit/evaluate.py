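"""Splitting, RMSE/R^2/CORR metrics and the multi-model benchmark harness."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .simulate import GAS_NAMES

__all__ = ["MetricTriple", "MetricsReport", "split_dataset",
           "compute_metrics", "run_benchmark", "plot_predictions"]


@dataclass(frozen=True)
class MetricTriple:
    rmse: float
    r2: float
    corr: float


@dataclass
class MetricsReport:
    """Per-gas and pooled RMSE (ppm), R^2 and Pearson correlation."""

    per_gas: dict[str, MetricTriple]
    pooled: MetricTriple
    n: int

    def to_frame(self) -> pd.DataFrame:
        rows = [{"gas": g, "rmse": m.rmse, "r2": m.r2, "corr": m.corr}
                for g, m in self.per_gas.items()]
        rows.append({"gas": "pooled", "rmse": self.pooled.rmse,
                     "r2": self.pooled.r2, "corr": self.pooled.corr})
        return pd.DataFrame(rows)


def split_dataset(samples, ratio: float = 0.8, seed: int | None = None):
    """Seeded uniform random partition; train size is floor(ratio * n)."""
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    if not 0.0 < ratio < 1.0:
        raise ValueError("ratio must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_train = int(np.floor(ratio * n))
    train_idx, test_idx = np.sort(order[:n_train]), np.sort(order[n_train:])
    if isinstance(samples, np.ndarray):
        return samples[train_idx], samples[test_idx]
    return ([samples[i] for i in train_idx], [samples[i] for i in test_idx])


def split_chronological(samples, ratio: float = 0.8):
    """First floor(ratio*n) samples train, the rest test (leakage-safe for
    overlapping sliding windows)."""
    n = len(samples)
    if n < 2:
        raise ValueError("need at least 2 samples to split")
    n_train = int(np.floor(ratio * n))
    return samples[:n_train], samples[n_train:]


def _triple(y: np.ndarray, yhat: np.ndarray) -> MetricTriple:
    rmse = float(np.sqrt(np.mean((yhat - y) ** 2)))
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    if ss_tot == 0.0:
        return MetricTriple(rmse, float("nan"), float("nan"))
    r2 = 1.0 - float(np.sum((yhat - y) ** 2)) / ss_tot
    sy, syh = y.std(), yhat.std()
    corr = (float("nan") if sy == 0 or syh == 0 else
            float(np.mean((y - y.mean()) * (yhat - yhat.mean())) / (sy * syh)))
    return MetricTriple(rmse, r2, corr)


def compute_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> MetricsReport:
    """RMSE, R^2 and CORR per gas plus pooled over all (sample, gas) pairs.

    Constant truth leaves R^2/CORR as NaN (undefined); RMSE is always
    reported.
    """
    y = np.asarray(y_true, dtype=float)
    yhat = np.asarray(y_pred, dtype=float)
    if y.shape != yhat.shape:
        raise ValueError("y_true and y_pred must have the same shape")
    if y.ndim == 1:
        y, yhat = y[:, None], yhat[:, None]
    if len(y) < 2:
        raise ValueError("need at least 2 predictions")
    names = (list(GAS_NAMES) if y.shape[1] == len(GAS_NAMES)
             else [f"target_{j}" for j in range(y.shape[1])])
    per_gas = {name: _triple(y[:, j], yhat[:, j])
               for j, name in enumerate(names)}
    pooled = _triple(y.ravel(), yhat.ravel())
    return MetricsReport(per_gas, pooled, int(y.size))


def run_benchmark(model_names, train, test, config, seeds=(0,),
                  verbose: bool = False) -> pd.DataFrame:
    """Train each named network on a shared split and report both splits.

    ``train``/``test`` are (X, y) array pairs on the *same* scaler;
    ``config`` carries the common hyperparameters (hidden sizes, batch,
    epochs, learning rate) shared by every model for fairness.  Returns one
    row per model x seed x split with RMSE, R2 and CORR columns.
    """
    from dataclasses import replace

    from .models import ConcentrationModel

    (X_tr, y_tr), (X_te, y_te) = train, test
    rows = []
    for name in model_names:
        for seed in seeds:
            cfg = replace(config, name=name, seed=int(seed),
                          length=X_tr.shape[1], channels=X_tr.shape[2])
            res = ConcentrationModel(X_tr, y_tr, cfg).fit(verbose=verbose)
            for split, X, y in (("train", X_tr, y_tr), ("test", X_te, y_te)):
                rep = res.evaluate(X, y)
                rows.append({"model": name, "seed": int(seed), "split": split,
                             "RMSE": rep.pooled.rmse, "R2": rep.pooled.r2,
                             "CORR": rep.pooled.corr})
            if verbose:
                print(f"{name} seed {seed}: "
                      f"test RMSE {rows[-1]['RMSE']:.3f} "
                      f"R2 {rows[-1]['R2']:.3f}")
    return pd.DataFrame(rows)


def plot_predictions(y_true, y_pred, gases=None, path=None):
    """Truth-vs-prediction traces per gas (matplotlib figure)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    y = np.asarray(y_true, float)
    yhat = np.asarray(y_pred, float)
    gases = gases or list(GAS_NAMES)[: y.shape[1]]
    fig, axes = plt.subplots(len(gases), 1, sharex=True,
                             figsize=(8, 1.8 * len(gases)))
    axes = np.atleast_1d(axes)
    for j, (ax, g) in enumerate(zip(axes, gases)):
        ax.plot(y[:, j], lw=1, label="true")
        ax.plot(yhat[:, j], lw=1, label="predicted")
        ax.set_ylabel(g, fontsize=7)
    axes[0].legend(loc="upper right", fontsize=7)
    axes[-1].set_xlabel("test sample")
    fig.tight_layout()
    if path is not None:
        fig.savefig(path, dpi=120)
        plt.close(fig)
    return fig
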