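"""Per-channel time- and frequency-domain features of sample windows.

Nine features per gas channel: six from the time domain (response integral,
differential, average differential, maximum, minimum, mean) and three from
the one-sided spectrum of the demeaned, Hann-windowed signal (barycenter
frequency, average frequency, maximum-power frequency).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .preprocess import SampleWindow
from .simulate import GAS_NAMES

__all__ = ["FEATURE_NAMES", "time_features", "freq_features",
           "extract_features", "feature_channel_map"]

#: deterministic feature order within each channel
FEATURE_NAMES = (
    "integral",
    "differential",
    "avg_differential",
    "maximum",
    "minimum",
    "mean",
    "f_barycenter",
    "f_average",
    "f_peak",
)


def time_features(series: np.ndarray, differential: str = "max") -> np.ndarray:
    """Six time-domain features.

    integral = sum(x)*dt at dt = 1 s; differential = the maximum first
    difference (``differential="net"`` uses last-first instead); average
    differential = mean absolute first difference; then max, min, mean.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 2:
        raise ValueError("need at least 2 samples for difference features")
    dx = np.diff(x)
    if differential == "max":
        diff = dx.max()
    elif differential == "net":
        diff = x[-1] - x[0]
    else:
        raise ValueError(f"unknown differential definition {differential!r}")
    return np.array([x.sum(), diff, np.abs(dx).mean(), x.max(), x.min(),
                     x.mean()])


def freq_features(series: np.ndarray, fs: float = 1.0) -> np.ndarray:
    """Barycenter, amplitude-weighted average and peak frequency (Hz).

    The series is demeaned and Hann-windowed before the FFT; an all-zero
    spectrum yields (0, 0, 0) with a warning.
    """
    x = np.asarray(series, dtype=float)
    if len(x) < 4:
        raise ValueError("need at least 4 samples for spectral features")
    x = (x - x.mean()) * np.hanning(len(x))
    spec = np.fft.rfft(x)
    amp = np.abs(spec)
    power = amp**2
    freqs = np.fft.rfftfreq(len(x), d=1.0 / fs)
    if power.sum() <= np.finfo(float).tiny:
        warnings.warn("all-zero spectrum: frequency features set to 0",
                      stacklevel=2)
        return np.zeros(3)
    barycenter = float((freqs * power).sum() / power.sum())
    average = float((freqs * amp).sum() / amp.sum())
    peak = float(freqs[np.argmax(power)])
    return np.array([barycenter, average, peak])


def feature_channel_map(channel_ids: list[str]) -> dict[str, str]:
    """Column name -> owning channel id, for sensor-level rank aggregation."""
    return {f"{cid}:{feat}": cid for cid in channel_ids for feat in FEATURE_NAMES}


def extract_features(windows: list[SampleWindow], channel_ids: list[str],
                     channel_subset: list[str] | None = None,
                     differential: str = "max") -> pd.DataFrame:
    """Build the feature table: 9 features per selected gas channel per window.

    Returns a DataFrame with columns ``<channel>:<feature>`` followed by the
    eight ``y_<gas>`` target columns.  Column order is deterministic:
    channels in the given order, features in :data:`FEATURE_NAMES` order.
    """
    if not windows:
        raise ValueError("no windows supplied")
    subset = channel_subset if channel_subset is not None else channel_ids
    if not subset:
        raise ValueError("empty channel subset")
    idx = {cid: i for i, cid in enumerate(channel_ids)}
    missing = [c for c in subset if c not in idx]
    if missing:
        raise KeyError(f"channels not in recording: {missing}")
    cols = [f"{cid}:{feat}" for cid in subset for feat in FEATURE_NAMES]
    rows = np.empty((len(windows), len(cols)))
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # flat traces are legitimate here
        for r, w in enumerate(windows):
            vals = []
            for cid in subset:
                series = w.values[:, idx[cid]]
                vals.append(time_features(series, differential))
                vals.append(freq_features(series))
            rows[r] = np.concatenate(vals)
    if np.isnan(rows).any():
        raise ValueError("feature extraction produced NaNs")
    df = pd.DataFrame(rows, columns=cols)
    targets = np.stack([w.target for w in windows])
    for j, g in enumerate(GAS_NAMES):
        df[f"y_{g}"] = targets[:, j]
    return df
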