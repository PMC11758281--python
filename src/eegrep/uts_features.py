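"""Univariate (per-channel) representations: raw concatenation, recurrence
plots, and time-domain/ERP features.

Each pipeline extracts information from every channel's univariate time
series independently and concatenates across channels:

* UTS      — the raw series, channel by channel: length C*T (3840 at 64x60).
* UTS-RP   — the flattened T x T recurrence plot per channel: length C*T*T
             (230400 at 64x60).  The recurrence plot holds the absolute
             amplitude difference between every pair of time points.
* UTS-TDF  — 10 time-domain features per channel: max, min, mean, variance,
             skewness, excess kurtosis, and the N1, P1, P2, P3 ERP peaks
             taken as window extrema: length 10*C (640 at 64 channels).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import stats

from .data_model import Epoch

__all__ = [
    "ErpWindows",
    "uts_vector",
    "recurrence_plot",
    "uts_rp_vector",
    "time_domain_features",
    "uts_tdf_vector",
    "TDF_NAMES",
]

TDF_NAMES = (
    "max", "min", "mean", "variance", "skewness", "kurtosis",
    "N1", "P1", "P2", "P3",
)


@dataclass(frozen=True)
class ErpWindows:
    """Inclusive 0-based index windows for the ERP peaks on the 60-step grid.

    N1 and P1 share the ~100 ms window (steps 13-16) with opposite extrema
    (minimum vs maximum); P2 covers 150-275 ms (17-24) and P3 250-500 ms
    (22-35).
    """

    N1: tuple[int, int] = (13, 16)
    P1: tuple[int, int] = (13, 16)
    P2: tuple[int, int] = (17, 24)
    P3: tuple[int, int] = (22, 35)

    @property
    def max_index(self) -> int:
        return max(self.N1[1], self.P1[1], self.P2[1], self.P3[1])


def _as_matrix(epoch: Epoch | np.ndarray) -> np.ndarray:
    if isinstance(epoch, Epoch):
        return epoch.values
    arr = np.asarray(epoch, dtype=float)
    if arr.ndim == 1:
        arr = arr[None, :]
    return arr


def _select(values: np.ndarray, channels: Sequence[int] | None) -> np.ndarray:
    if channels is None:
        return values
    channels = list(channels)
    if any(c < 0 or c >= values.shape[0] for c in channels):
        raise ValueError(f"channel selection {channels} outside 0..{values.shape[0] - 1}")
    return values[channels]


def uts_vector(epoch: Epoch | np.ndarray, channels: Sequence[int] | None = None) -> np.ndarray:
    """Row-major concatenation of the univariate series, channel by channel."""
    return _select(_as_matrix(epoch), channels).ravel()


def recurrence_plot(series: np.ndarray) -> np.ndarray:
    """T x T matrix of absolute amplitude differences between time points.

    Symmetric with a zero diagonal; being distances on the real line, its
    entries satisfy the triangle inequality.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size < 1:
        raise ValueError("series must have at least one sample")
    return np.abs(x[:, None] - x[None, :])


def uts_rp_vector(epoch: Epoch | np.ndarray, channels: Sequence[int] | None = None) -> np.ndarray:
    """Flattened per-channel recurrence plots, concatenated across channels."""
    values = _select(_as_matrix(epoch), channels)
    return np.concatenate([recurrence_plot(row).ravel() for row in values])


def time_domain_features(series: np.ndarray, windows: ErpWindows = ErpWindows()) -> np.ndarray:
    """The 10 time-domain features of one univariate series.

    Order: [max, min, mean, variance, skewness, kurtosis, N1, P1, P2, P3].
    N1 is the signed minimum over its window; P1/P2/P3 are window maxima.
    Skewness and excess kurtosis of a zero-variance series are defined as 0.
    """
    x = np.asarray(series, dtype=float).ravel()
    if x.size <= windows.max_index:
        raise ValueError(
            f"series of length {x.size} too short for ERP windows "
            f"(need > {windows.max_index})"
        )
    if np.ptp(x) == 0.0:  # constant series: 0/0 moment ratios defined as 0
        var = skew = kurt = 0.0
    else:
        var = float(np.var(x))
        skew = float(stats.skew(x))
        kurt = float(stats.kurtosis(x))  # excess kurtosis: Gaussian -> 0
    n1 = float(np.min(x[windows.N1[0]: windows.N1[1] + 1]))
    p1 = float(np.max(x[windows.P1[0]: windows.P1[1] + 1]))
    p2 = float(np.max(x[windows.P2[0]: windows.P2[1] + 1]))
    p3 = float(np.max(x[windows.P3[0]: windows.P3[1] + 1]))
    return np.array(
        [float(np.max(x)), float(np.min(x)), float(np.mean(x)), var, skew, kurt,
         n1, p1, p2, p3]
    )


def uts_tdf_vector(epoch: Epoch | np.ndarray, channels: Sequence[int] | None = None,
                   windows: ErpWindows = ErpWindows()) -> np.ndarray:
    """Per-channel time-domain features concatenated: 10 per channel."""
    values = _select(_as_matrix(epoch), channels)
    return np.concatenate([time_domain_features(row, windows) for row in values])
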