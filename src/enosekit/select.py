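"""Ensemble feature ranking and sensor-channel selection.

Four rankers — Pearson correlation and binned mutual information (filter
methods), random-forest impurity importance (embedded) and linear SVM
recursive feature elimination (wrapper) — each produce a 1..m ranking
(1 = most informative, ties get the average rank).  The ensemble rank is
the per-feature mean over methods, and a sensor's rank is the mean of its
nine feature ranks; the best k gas channels, plus the environment
reference channels, form the model input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestRegressor
from sklearn.feature_selection import RFE
from sklearn.svm import LinearSVR

__all__ = ["RankMatrix", "METHODS", "rank_features", "ensemble_rank",
           "sensor_rank", "select_channels", "build_rank_matrix"]

METHODS = ("pearson", "mic", "rf", "svmrfe")


def _split_table(table: pd.DataFrame) -> tuple[np.ndarray, np.ndarray, list[str]]:
    feat_cols = [c for c in table.columns if not c.startswith("y_")]
    y_cols = [c for c in table.columns if c.startswith("y_")]
    if not y_cols:
        raise ValueError("feature table has no y_ target columns")
    return (table[feat_cols].to_numpy(float), table[y_cols].to_numpy(float),
            feat_cols)


def _scores_to_ranks(scores: np.ndarray) -> np.ndarray:
    """Higher score -> better (smaller) rank; ties get the average rank."""
    return rankdata(-scores, method="average")


def _pearson_scores(X: np.ndarray, Y: np.ndarray, aggregate: str) -> np.ndarray:
    Xc = X - X.mean(axis=0)
    Yc = Y - Y.mean(axis=0)
    sx = Xc.std(axis=0)
    sy = Yc.std(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (Xc.T @ Yc) / len(X) / np.outer(sx, sy)
    r = np.abs(np.nan_to_num(r, nan=0.0))  # constant columns score worst
    return r.max(axis=1) if aggregate == "max" else r.mean(axis=1)


def _binned_mi(x: np.ndarray, y: np.ndarray, bins: int) -> float:
    joint, _, _ = np.histogram2d(x, y, bins=bins)
    p = joint / joint.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (px @ py)[nz])).sum())


def _mi_scores(X: np.ndarray, Y: np.ndarray, aggregate: str,
               bins: int | None = None) -> np.ndarray:
    n = len(X)
    bins = bins or max(int(np.sqrt(n / 5)), 4)
    out = np.empty((X.shape[1], Y.shape[1]))
    for i in range(X.shape[1]):
        if np.ptp(X[:, i]) == 0:
            out[i] = 0.0  # constant feature carries no information
            continue
        for j in range(Y.shape[1]):
            out[i, j] = _binned_mi(X[:, i], Y[:, j], bins)
    return out.max(axis=1) if aggregate == "max" else out.mean(axis=1)


def _rf_scores(X: np.ndarray, Y: np.ndarray, seed: int,
               n_estimators: int) -> np.ndarray:
    forest = RandomForestRegressor(n_estimators=n_estimators,
                                   random_state=seed, n_jobs=1)
    forest.fit(X, Y)
    return forest.feature_importances_


def _svmrfe_ranks(X: np.ndarray, Y: np.ndarray, seed: int) -> np.ndarray:
    # standardize so SVR weight magnitudes are comparable across features
    mu, sd = X.mean(axis=0), X.std(axis=0)
    Xs = (X - mu) / np.where(sd == 0, 1.0, sd)
    ranks = np.zeros(X.shape[1])
    for j in range(Y.shape[1]):
        est = LinearSVR(C=1.0, max_iter=5000, random_state=seed,
                        dual="auto", tol=1e-3)
        rfe = RFE(est, n_features_to_select=1, step=0.1)
        rfe.fit(Xs, Y[:, j])
        ranks += rfe.ranking_.astype(float)
    return rankdata(ranks / Y.shape[1], method="average")


def rank_features(method: str, table: pd.DataFrame, seed: int = 0,
                  aggregate: str = "max",
                  rf_estimators: int = 200) -> np.ndarray:
    """Rank all feature columns of a table by one method (1 = best).

    Multi-target aggregation for the filter methods takes the best score
    over the eight gases (``aggregate="mean"`` averages instead).
    """
    X, Y, feat_cols = _split_table(table)
    if len(X) < 20:
        raise ValueError("need at least 20 samples to rank features")
    if method == "pearson":
        return _scores_to_ranks(_pearson_scores(X, Y, aggregate))
    if method == "mic":
        return _scores_to_ranks(_mi_scores(X, Y, aggregate))
    if method == "rf":
        return _scores_to_ranks(_rf_scores(X, Y, seed, rf_estimators))
    if method == "svmrfe":
        return _svmrfe_ranks(X, Y, seed)
    raise ValueError(f"unknown ranking method {method!r}")


def ensemble_rank(per_method: np.ndarray) -> np.ndarray:
    """Elementwise mean of the per-method rank rows (N x m -> m)."""
    per_method = np.asarray(per_method, dtype=float)
    if per_method.ndim != 2:
        raise ValueError("per_method must be a 2-D N x m array")
    return per_method.mean(axis=0)


def sensor_rank(ensemble: np.ndarray, feature_names: list[str],
                channel_map: dict[str, str]) -> dict[str, float]:
    """Mean ensemble rank of each sensor's features."""
    unmapped = [f for f in feature_names if f not in channel_map]
    if unmapped:
        raise KeyError(f"features not mapped to a sensor: {unmapped[:3]}")
    sums: dict[str, list[float]] = {}
    for name, r in zip(feature_names, ensemble):
        sums.setdefault(channel_map[name], []).append(float(r))
    return {cid: float(np.mean(v)) for cid, v in sums.items()}


def _channel_sort_key(cid: str) -> tuple:
    digits = "".join(ch for ch in cid if ch.isdigit())
    return (cid[0], int(digits) if digits else 0, cid)


def select_channels(sensor_ranks: dict[str, float], k: int,
                    always_include: tuple[str, ...] = ("S22", "S23")
                    ) -> list[str]:
    """Best-k gas channels in rank order, then the always-included channels.

    Ties are broken by channel id so the selection is deterministic.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    candidates = [c for c in sensor_ranks if c not in always_include]
    if k > len(candidates):
        raise ValueError(f"k={k} exceeds the {len(candidates)} gas channels")
    ordered = sorted(candidates,
                     key=lambda c: (sensor_ranks[c], _channel_sort_key(c)))
    return ordered[:k] + list(always_include)


@dataclass
class RankMatrix:
    """All ranking artifacts: per-method, ensemble and sensor-level."""

    methods: list[str]
    feature_names: list[str]
    per_method: np.ndarray  # (N, m) ranks, 1 = best
    ensemble: np.ndarray  # (m,)
    sensor: dict[str, float]
    channel_map: dict[str, str]

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame({"feature": self.feature_names})
        for name, row in zip(self.methods, self.per_method):
            df[f"rank_{name}"] = row
        df["rank_ensemble"] = self.ensemble
        df["sensor"] = [self.channel_map[f] for f in self.feature_names]
        return df


def build_rank_matrix(table: pd.DataFrame, channel_map: dict[str, str],
                      seed: int = 0, methods: tuple[str, ...] = METHODS,
                      aggregate: str = "max") -> RankMatrix:
    """Run every ranker on a feature table and aggregate to sensor ranks."""
    feat_cols = [c for c in table.columns if not c.startswith("y_")]
    per_method = np.stack([
        rank_features(m, table, seed=seed, aggregate=aggregate)
        for m in methods
    ])
    ens = ensemble_rank(per_method)
    sens = sensor_rank(ens, feat_cols, channel_map)
    return RankMatrix(list(methods), feat_cols, per_method, ens, sens,
                      dict(channel_map))
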