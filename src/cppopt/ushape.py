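"""U-shape fitting: binned PRx vs a driver axis, optimum and CA limits.

PRx values are binned against CPP, ABP or ICP (5-mmHg bins aligned to
multiples of the bin width) and the bin means are fit by a count-weighted
quadratic PRx ~ a x^2 + b x + c0.  For an upward-opening fit the vertex
-b/(2a) inside the observed bin range is the optimum (CPPopt / ABPopt), and
the crossings of the fitted curve with the PRx = +0.3 threshold give the
lower and upper limits of autoregulation (LLCA / ULCA).  For the ICP axis
only the upper crossing is meaningful and no optimum is reported, since an
"optimal ICP" is not a treatment target.

``select_segments`` implements the R^2-driven inclusion rule: artifact-free
informative segments form the base set; remaining artifact-free segments
are added one at a time, in chronological order, only when they strictly
increase the R^2 of the fit; artifact-distorted segments never enter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .io import ValidationError
from .prx import PRxSeries
from .segments import Segment

__all__ = ["AXES", "PRxBins", "UShapeFit", "bin_prx", "fit_ushape", "select_segments"]

AXES = ("cpp", "abp", "icp")
THRESHOLD = 0.3
#: a fit needs at least this many surviving bins ...
MIN_BINS = 3
#: ... spanning at least this many mmHg
MIN_SPAN = 10.0


@dataclass
class PRxBins:
    axis: str
    bin_width: float
    centers: np.ndarray
    means: np.ndarray
    counts: np.ndarray
    n_samples: int

    @property
    def fit_possible(self) -> bool:
        return (self.centers.size >= MIN_BINS
                and (self.centers.max() - self.centers.min()) >= MIN_SPAN)


@dataclass
class UShapeFit:
    """Quadratic fit summary; absent quantities are None and NaN for coefs."""

    axis: str
    a: float
    b: float
    c0: float
    r_squared: float
    opt_value: float | None
    llca: float | None
    ulca: float | None
    valid: bool
    threshold: float
    bin_width: float
    bin_centers: np.ndarray
    bin_means: np.ndarray
    bin_counts: np.ndarray
    chosen_segments: tuple[int, ...] | None = None

    @property
    def n_bins(self) -> int:
        return self.bin_centers.size

    @property
    def has_target(self) -> bool:
        """True when the fit offers an optimum or either CA limit."""
        if not self.valid:
            return False
        if self.axis == "icp":
            return self.ulca is not None
        return any(v is not None for v in (self.opt_value, self.llca, self.ulca))

    def to_dict(self) -> dict:
        return {
            "axis": self.axis, "a": self.a, "b": self.b, "c0": self.c0,
            "r_squared": self.r_squared, "opt_value": self.opt_value,
            "llca": self.llca, "ulca": self.ulca, "valid": self.valid,
            "n_bins": self.n_bins,
            "chosen_segments": list(self.chosen_segments)
            if self.chosen_segments is not None else None,
        }


def _invalid_fit(axis: str, threshold: float, bin_width: float,
                 bins: PRxBins | None = None) -> UShapeFit:
    empty = np.empty(0)
    return UShapeFit(
        axis=axis, a=math.nan, b=math.nan, c0=math.nan, r_squared=math.nan,
        opt_value=None, llca=None, ulca=None, valid=False,
        threshold=threshold, bin_width=bin_width,
        bin_centers=bins.centers if bins is not None else empty,
        bin_means=bins.means if bins is not None else empty,
        bin_counts=bins.counts if bins is not None else empty,
    )


def bin_prx(prx_series: PRxSeries, axis: str, bin_width: float = 5.0,
            min_count: int = 5) -> PRxBins:
    """Fixed-width bins of PRx against a driver axis.

    Bins are aligned to multiples of ``bin_width`` (a sample at 62 mmHg with
    width 5 falls in [60, 65)); bins holding fewer than ``min_count``
    samples are dropped.
    """
    if axis not in AXES:
        raise ValidationError(f"axis must be one of {AXES}")
    x = {"cpp": prx_series.cpp_mean, "abp": prx_series.abp_mean,
         "icp": prx_series.icp_mean}[axis]
    y = prx_series.prx
    good = np.isfinite(x) & np.isfinite(y)
    x, y = x[good], y[good]
    if x.size == 0:
        return PRxBins(axis, bin_width, np.empty(0), np.empty(0),
                       np.empty(0, int), 0)
    idx = np.floor(x / bin_width).astype(int)
    uniq, inv = np.unique(idx, return_inverse=True)
    counts = np.bincount(inv)
    sums = np.bincount(inv, weights=y)
    keep = counts >= min_count
    centers = (uniq[keep] + 0.5) * bin_width
    return PRxBins(axis, bin_width, centers, sums[keep] / counts[keep],
                   counts[keep].astype(int), int(counts[keep].sum()))


def fit_ushape(bins: PRxBins, threshold: float = THRESHOLD,
               min_r2: float = 0.0) -> UShapeFit:
    """Count-weighted quadratic fit of the bin means with optimum and limits.

    The vertex is only reported when it lies inside the observed bin range
    (extrapolated optima are suppressed); the threshold crossings are the
    real roots of a x^2 + b x + (c0 - threshold) that fall inside the range,
    assigned as the lower/upper crossing around the vertex.
    """
    if not bins.fit_possible:
        return _invalid_fit(bins.axis, threshold, bins.bin_width, bins)

    w = np.sqrt(bins.counts.astype(float))
    a, b, c0 = np.polyfit(bins.centers, bins.means, 2, w=w)
    yhat = np.polyval([a, b, c0], bins.centers)
    wm = np.average(bins.means, weights=bins.counts)
    ss_res = float(np.sum(bins.counts * (bins.means - yhat) ** 2))
    ss_tot = float(np.sum(bins.counts * (bins.means - wm) ** 2))
    r2 = 0.0 if ss_tot <= 0 else max(0.0, min(1.0, 1.0 - ss_res / ss_tot))

    fit = UShapeFit(
        axis=bins.axis, a=float(a), b=float(b), c0=float(c0), r_squared=r2,
        opt_value=None, llca=None, ulca=None, valid=False, threshold=threshold,
        bin_width=bins.bin_width, bin_centers=bins.centers,
        bin_means=bins.means, bin_counts=bins.counts)

    if a <= 0 or r2 < min_r2:
        return fit  # recorded, but invalid: no optimum, no limits
    fit.valid = True

    lo, hi = float(bins.centers.min()), float(bins.centers.max())
    vertex = -b / (2 * a)
    if bins.axis != "icp" and lo <= vertex <= hi:
        fit.opt_value = float(vertex)
    disc = b * b - 4 * a * (c0 - threshold)
    if disc > 0:
        root_lo = (-b - math.sqrt(disc)) / (2 * a)
        root_hi = (-b + math.sqrt(disc)) / (2 * a)
        if bins.axis != "icp" and lo <= root_lo <= hi:
            fit.llca = float(root_lo)
        if lo <= root_hi <= hi:
            fit.ulca = float(root_hi)
    return fit


def _fit_score(fit: UShapeFit | None) -> float:
    if fit is None or not fit.valid or not np.isfinite(fit.r_squared):
        return -math.inf
    return fit.r_squared


def select_segments(
    segments: list[Segment],
    prx_series: PRxSeries,
    axis: str,
    *,
    bin_width: float = 5.0,
    min_count: int = 5,
    threshold: float = THRESHOLD,
    min_r2: float = 0.0,
) -> tuple[list[int], UShapeFit | None]:
    """R^2-driven greedy segment inclusion for one 2-h window.

    Returns the chosen segment indices and the final fit.  With no
    artifact-free informative segment there is nothing to anchor the fit
    and (``[]``, None) is returned; the window counts as non-yield time.
    """
    segs = sorted(segments, key=lambda s: s.start_s)

    def _fit_for(chosen: list[Segment]) -> UShapeFit:
        mask = np.zeros(len(prx_series), dtype=bool)
        for seg in chosen:
            mask |= (prx_series.t_end > seg.start_s) & (prx_series.t_end <= seg.end_s)
        return fit_ushape(bin_prx(prx_series.subset(mask), axis, bin_width,
                                  min_count), threshold, min_r2)

    base = [s for s in segs if s.is_artifact_free and s.is_informative]
    if not base:
        return [], None
    candidates = [s for s in segs if s.is_artifact_free and not s.is_informative]

    current = list(base)
    fit = _fit_for(current)
    for cand in candidates:  # single chronological pass, inclusions permanent
        trial = sorted(current + [cand], key=lambda s: s.start_s)
        trial_fit = _fit_for(trial)
        if trial_fit.valid and _fit_score(trial_fit) > _fit_score(fit):
            current, fit = trial, trial_fit
    fit = replace(fit, chosen_segments=tuple(s.segment_index for s in current))
    return [s.segment_index for s in current], fit
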