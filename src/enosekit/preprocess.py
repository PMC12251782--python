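"""Signal conditioning: lag alignment, Kalman + Savitzky-Golay filtering,
min-max scaling and sliding-window sample extraction.

The filter chain is applied per channel in a fixed order — scalar
random-walk Kalman filter first, Savitzky-Golay smoother second — after an
optional lag shift that re-aligns the sensor response with the true
concentration input.  Environment channels are smoothed but never shifted.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.signal import savgol_filter

from .simulate import GAS_NAMES, ArrayRecording

__all__ = [
    "FilterConfig",
    "Scaler",
    "SampleWindow",
    "estimate_lag",
    "kalman_smooth",
    "savgol_smooth",
    "preprocess_recording",
    "fit_scaler",
    "windowize",
    "save_windows",
    "load_windows",
]


@dataclass(frozen=True)
class FilterConfig:
    """Lag + filter hyperparameters.

    ``sg_window=1`` disables the Savitzky-Golay stage; ``kalman_q=None``
    disables the Kalman stage (useful for identity configurations).
    """

    lag_s: int = 0
    kalman_q: float | None = 10.0
    kalman_r: float = 4.0
    sg_window: int = 11
    sg_order: int = 3

    def __post_init__(self):
        if self.lag_s < 0:
            raise ValueError("lag_s must be nonnegative")
        if self.kalman_q is not None:
            if self.kalman_q <= 0 or self.kalman_r <= 0:
                raise ValueError("kalman_q and kalman_r must be positive")
        if self.sg_window != 1:
            if self.sg_window % 2 == 0:
                raise ValueError("sg_window must be odd")
            if self.sg_order >= self.sg_window:
                raise ValueError("sg_order must be smaller than sg_window")


def estimate_lag(truth_series: np.ndarray, response_series: np.ndarray,
                 max_lag: int) -> int:
    """Delay (s) of the response behind the concentration input.

    Returns the lag in ``[0, max_lag]`` maximising the Pearson correlation
    between ``truth[:-lag]`` and ``response[lag:]``.
    """
    x = np.asarray(truth_series, dtype=float)
    y = np.asarray(response_series, dtype=float)
    if len(x) != len(y):
        raise ValueError("series must have equal length")
    if len(x) < 2 * max_lag:
        raise ValueError("series too short for the requested max_lag")
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("constant series: cross-correlation undefined")
    best_lag, best_r = 0, -np.inf
    for lag in range(max_lag + 1):
        a = x[: len(x) - lag] if lag else x
        b = y[lag:]
        sa, sb = np.std(a), np.std(b)
        r = -np.inf if sa == 0 or sb == 0 else float(
            np.mean((a - a.mean()) * (b - b.mean())) / (sa * sb))
        if r > best_r:
            best_lag, best_r = lag, r
    return best_lag


def kalman_smooth(series: np.ndarray, q: float, r: float) -> np.ndarray:
    """Scalar random-walk Kalman filter (predict/update at every step)."""
    if q <= 0 or r <= 0:
        raise ValueError("q and r must be positive")
    z = np.asarray(series, dtype=float)
    out = np.empty_like(z)
    x, p = z[0], r
    out[0] = x
    for t in range(1, len(z)):
        p = p + q
        k = p / (p + r)
        x = x + k * (z[t] - x)
        p = (1.0 - k) * p
        out[t] = x
    return out


def savgol_smooth(series: np.ndarray, window: int, order: int) -> np.ndarray:
    """Savitzky-Golay least-squares polynomial smoother (edge-fitted)."""
    z = np.asarray(series, dtype=float)
    if window % 2 == 0:
        raise ValueError("window must be odd")
    if order >= window:
        raise ValueError("order must be smaller than window")
    if len(z) < window:
        raise ValueError("series shorter than the filter window")
    return savgol_filter(z, window_length=window, polyorder=order, mode="interp")


def _shift_back(series: np.ndarray, lag: int) -> np.ndarray:
    """Advance the response by ``lag`` samples, repeating the final value."""
    if lag == 0:
        return series
    out = np.empty_like(series)
    out[:-lag] = series[lag:]
    out[-lag:] = series[-1]
    return out


def preprocess_recording(recording: ArrayRecording, config: FilterConfig,
                         env_channels: tuple[str, ...] = ("S22", "S23")
                         ) -> ArrayRecording:
    """Lag-align then filter every channel of a recording.

    Gas channels are shifted back by ``lag_s`` and passed through the
    Kalman → Savitzky-Golay chain; environment channels are filtered only.
    """
    out = recording.channels.astype(float).copy()
    for i, cid in enumerate(recording.channel_ids):
        ch = out[:, i]
        if cid not in env_channels and config.lag_s:
            ch = _shift_back(ch, config.lag_s)
        if config.kalman_q is not None:
            ch = kalman_smooth(ch, config.kalman_q, config.kalman_r)
        if config.sg_window != 1:
            ch = savgol_smooth(ch, config.sg_window, config.sg_order)
        out[:, i] = ch
    return recording.copy_with(out)


@dataclass
class Scaler:
    """Per-column min-max scaler: x -> (x - min) / (max - min).

    Fitted on training data only; values outside the fitted range are kept
    (no clipping), so transformed test data may fall outside [0, 1].
    Constant columns map to 0 and raise a warning at fit time.
    """

    col_min: np.ndarray
    col_max: np.ndarray

    @property
    def _range(self) -> np.ndarray:
        rng = self.col_max - self.col_min
        return np.where(rng == 0.0, 1.0, rng)

    def transform(self, x: np.ndarray) -> np.ndarray:
        return (np.asarray(x, dtype=float) - self.col_min) / self._range

    def inverse_transform(self, x: np.ndarray) -> np.ndarray:
        return np.asarray(x, dtype=float) * self._range + self.col_min

    def to_dict(self) -> dict:
        return {"min": self.col_min.tolist(), "max": self.col_max.tolist()}

    @classmethod
    def from_dict(cls, d: dict) -> "Scaler":
        return cls(np.asarray(d["min"], float), np.asarray(d["max"], float))


def fit_scaler(data: np.ndarray | list) -> Scaler:
    """Fit a per-column Scaler.

    Accepts a 2-D array (rows x columns), a 3-D stack of windows
    (n x L x C, scaled per channel), or a list of SampleWindow.
    """
    if isinstance(data, list):
        data = np.stack([w.values for w in data])
    data = np.asarray(data, dtype=float)
    if data.size == 0:
        raise ValueError("cannot fit a scaler on an empty set")
    flat = data.reshape(-1, data.shape[-1])
    lo, hi = flat.min(axis=0), flat.max(axis=0)
    if np.any(lo == hi):
        const = np.flatnonzero(lo == hi)
        warnings.warn(f"constant column(s) {const.tolist()} map to 0",
                      stacklevel=2)
    return Scaler(lo, hi)


@dataclass
class SampleWindow:
    """A fixed-length slice of a recording with its 8-gas target vector."""

    values: np.ndarray  # (L, C)
    target: np.ndarray  # (8,) ppm
    origin: tuple[str, int] = ("", 0)  # recording id, start index

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.target = np.asarray(self.target, dtype=float)
        if self.target.shape != (len(GAS_NAMES),):
            raise ValueError("target must be an 8-vector")


def windowize(recording: ArrayRecording, length: int, stride: int,
              labeling: str = "last", recording_id: str = "") -> list[SampleWindow]:
    """Slice a recording into overlapping windows.

    ``labeling="last"`` (default) takes the true concentration at the final
    step of each window — the online-detector convention; ``"mean"`` averages
    the truth over the window.
    """
    T = len(recording)
    if length > T:
        raise ValueError("recording shorter than the window length")
    if stride < 1:
        raise ValueError("stride must be >= 1")
    if labeling not in ("last", "mean"):
        raise ValueError(f"unknown labeling {labeling!r}")
    windows = []
    for start in range(0, T - length + 1, stride):
        vals = recording.channels[start : start + length]
        if labeling == "last":
            tgt = recording.truth[start + length - 1]
        else:
            tgt = recording.truth[start : start + length].mean(axis=0)
        windows.append(SampleWindow(vals.copy(), tgt.copy(),
                                    (recording_id, start)))
    return windows


def save_windows(windows: list[SampleWindow], directory,
                 scaler: Scaler | None = None, stride: int | None = None,
                 channel_ids: list[str] | None = None) -> None:
    """Serialize windows as CSV shards plus a JSON manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "n_windows": len(windows),
        "length": int(windows[0].values.shape[0]),
        "n_channels": int(windows[0].values.shape[1]),
        "stride": stride,
        "channel_ids": channel_ids,
        "scaler": scaler.to_dict() if scaler is not None else None,
        "gases": list(GAS_NAMES),
    }
    (directory / "manifest.json").write_text(json.dumps(manifest, indent=2))
    for i, w in enumerate(windows):
        header = ",".join(channel_ids or
                          [f"c{j}" for j in range(w.values.shape[1])])
        tgt = ",".join(repr(float(v)) for v in w.target)
        with open(directory / f"window_{i:05d}.csv", "w") as fh:
            fh.write(f"# target,{tgt}\n# origin,{w.origin[0]},{w.origin[1]}\n")
            fh.write(header + "\n")
            np.savetxt(fh, w.values, delimiter=",")


def load_windows(directory) -> tuple[list[SampleWindow], Scaler | None]:
    directory = Path(directory)
    manifest = json.loads((directory / "manifest.json").read_text())
    windows = []
    for i in range(manifest["n_windows"]):
        path = directory / f"window_{i:05d}.csv"
        with open(path) as fh:
            tgt_line = fh.readline().strip().split(",")
            origin_line = fh.readline().strip().split(",")
        target = np.asarray([float(v) for v in tgt_line[1:]])
        values = np.loadtxt(path, delimiter=",", skiprows=3)
        windows.append(SampleWindow(values, target,
                                    (origin_line[1], int(origin_line[2]))))
    scaler = (Scaler.from_dict(manifest["scaler"])
              if manifest.get("scaler") else None)
    return windows, scaler
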