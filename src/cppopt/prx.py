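"""Cerebral perfusion pressure and the pressure reactivity index (PRx).

PRx is the moving Pearson correlation between slow ABP and ICP variations:
both mean series are first averaged into 10-s bins to suppress pulse and
respiratory components, then correlated over a sliding 5-min (or longer)
window.  Negative PRx indicates intact cerebrovascular autoregulation,
positive PRx impaired autoregulation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MonitoringRecord, ValidationError

__all__ = ["PRxParams", "PRxSeries", "compute_cpp", "compute_prx"]


@dataclass(frozen=True)
class PRxParams:
    """Windowing parameters of the PRx estimator.

    The correlation window must hold at least three averaging intervals and
    both the window and the update step must be integer multiples of the
    averaging interval.  A 10-s bin is only used when at least
    ``min_valid_fraction`` of its samples are present.
    """

    avg_interval_s: float = 10.0
    corr_window_s: float = 300.0
    step_s: float = 10.0
    min_valid_fraction: float = 0.75

    def __post_init__(self) -> None:
        if self.avg_interval_s <= 0:
            raise ValidationError("avg_interval_s must be positive")
        for name in ("corr_window_s", "step_s"):
            val = getattr(self, name)
            if abs(val / self.avg_interval_s - round(val / self.avg_interval_s)) > 1e-9:
                raise ValidationError(f"{name} must be a multiple of avg_interval_s")
        if self.corr_window_s < 3 * self.avg_interval_s:
            raise ValidationError("corr_window_s must span at least 3 averaging intervals")
        if not (0 < self.min_valid_fraction <= 1):
            raise ValidationError("min_valid_fraction must lie in (0, 1]")

    @property
    def window_bins(self) -> int:
        return int(round(self.corr_window_s / self.avg_interval_s))

    @property
    def step_bins(self) -> int:
        return int(round(self.step_s / self.avg_interval_s))


@dataclass
class PRxSeries:
    """Windowed PRx with co-registered mean CPP/ABP/ICP per window.

    ``t_end`` marks right-aligned, half-open windows ``(t_end - W, t_end]``.
    Missing windows (invalid bins, zero variance) carry NaN.
    """

    t_end: np.ndarray
    prx: np.ndarray
    cpp_mean: np.ndarray
    abp_mean: np.ndarray
    icp_mean: np.ndarray
    params: PRxParams = field(default_factory=PRxParams)

    def __post_init__(self) -> None:
        self.t_end = np.asarray(self.t_end, float)
        for name in ("prx", "cpp_mean", "abp_mean", "icp_mean"):
            arr = np.asarray(getattr(self, name), float)
            if arr.size != self.t_end.size:
                raise ValidationError(f"{name} length mismatch")
            setattr(self, name, arr)
        finite = np.isfinite(self.prx)
        if np.any(np.abs(self.prx[finite]) > 1 + 1e-9):
            raise ValidationError("PRx values must lie in [-1, 1]")

    def __len__(self) -> int:
        return self.t_end.size

    def subset(self, mask: np.ndarray) -> "PRxSeries":
        return PRxSeries(
            t_end=self.t_end[mask],
            prx=self.prx[mask],
            cpp_mean=self.cpp_mean[mask],
            abp_mean=self.abp_mean[mask],
            icp_mean=self.icp_mean[mask],
            params=self.params,
        )

    def window(self, start_s: float, end_s: float) -> "PRxSeries":
        """Samples whose window end time falls in (start_s, end_s]."""
        return self.subset((self.t_end > start_s) & (self.t_end <= end_s))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t_end": self.t_end, "prx": self.prx, "cpp_mean": self.cpp_mean,
             "abp_mean": self.abp_mean, "icp_mean": self.icp_mean})


def compute_cpp(record: MonitoringRecord) -> np.ndarray:
    """CPP = mean ABP - mean ICP, elementwise; NaN propagates."""
    return record.abp_mean - record.icp_mean


def _bin_means(x: np.ndarray, bin_n: int, min_valid_fraction: float):
    n_bins = x.size // bin_n
    xr = x[: n_bins * bin_n].reshape(n_bins, bin_n)
    finite = np.isfinite(xr)
    count = finite.sum(axis=1)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        means = np.nanmean(xr, axis=1)
    valid = count >= min_valid_fraction * bin_n
    return means, valid


def compute_prx(record: MonitoringRecord, params: PRxParams = PRxParams()) -> PRxSeries:
    """Compute the PRx series of a monitoring record.

    A window is missing (NaN) when any of its 10-s bins is invalid or when
    either binned channel has zero variance within the window -- a flat
    channel carries no autoregulation information, so 0/0 is never coerced
    to +/-1 or to 0.
    """
    bin_n = int(round(params.avg_interval_s / record.sample_period_s))
    abp_b, abp_ok = _bin_means(record.abp_mean, bin_n, params.min_valid_fraction)
    icp_b, icp_ok = _bin_means(record.icp_mean, bin_n, params.min_valid_fraction)
    n_bins = abp_b.size
    wb, sb = params.window_bins, params.step_bins

    empty = PRxSeries(
        t_end=np.empty(0), prx=np.empty(0), cpp_mean=np.empty(0),
        abp_mean=np.empty(0), icp_mean=np.empty(0), params=params)
    if n_bins < wb:
        warnings.warn("record shorter than one correlation window; empty PRx series",
                      stacklevel=2)
        return empty

    starts = np.arange(0, n_bins - wb + 1, sb)
    sw = np.lib.stride_tricks.sliding_window_view
    A = sw(abp_b, wb)[starts]
    I = sw(icp_b, wb)[starts]
    ok = (sw(abp_ok, wb)[starts] & sw(icp_ok, wb)[starts]).all(axis=1)

    Am = A - A.mean(axis=1, keepdims=True)
    Im = I - I.mean(axis=1, keepdims=True)
    va = np.einsum("ij,ij->i", Am, Am)
    vi = np.einsum("ij,ij->i", Im, Im)
    cov = np.einsum("ij,ij->i", Am, Im)
    denom = np.sqrt(va * vi)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, cov / np.where(denom > 0, denom, 1.0), np.nan)
    r = np.where(ok & (denom > 0), r, np.nan)
    r = np.clip(r, -1.0, 1.0)

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        abp_w = np.nanmean(A, axis=1)
        icp_w = np.nanmean(I, axis=1)
    t0 = record.t[0]
    t_end = t0 + (starts + wb) * params.avg_interval_s
    return PRxSeries(
        t_end=t_end, prx=r, cpp_mean=abp_w - icp_w,
        abp_mean=abp_w, icp_mean=icp_w, params=params)
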