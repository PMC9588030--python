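"""Per-segment feature vectors for the two segment classifiers.

X1 (artifact detection) summarizes the pulse amplitude d = sys - dia per
channel: its minimum and mean, the mean absolute first difference, and the
fraction of segment time spent below the 5 and 10 mmHg thresholds -- a
damped or flushed arterial line collapses the pulse amplitude long before
it corrupts the mean.

X2 (informative-segment recognition) captures slow-wave content: the
standard deviation of each mean series after centered moving-average
filtering at 1, 2, 3 and 4 minutes, plus the raw channel means.  B-waves
(30-120 s periods) survive the short filters but are averaged away by the
long ones, so the decay of the filtered SD across window lengths encodes
slow-wave amplitude.
"""

from __future__ import annotations

from dataclasses import dataclass, fields

import numpy as np
import pandas as pd

from .io import MonitoringRecord
from .segments import Segment

__all__ = [
    "ArtifactFeatures",
    "InformativeFeatures",
    "artifact_features",
    "informative_features",
    "segment_feature_table",
]

PULSE_THRESHOLDS = (5.0, 10.0)  # mmHg
FILTER_WINDOWS_S = (60, 120, 180, 240)
#: minimum fraction of usable samples for a feature vector to exist
MIN_VALID_FRACTION = 0.5


@dataclass(frozen=True)
class ArtifactFeatures:
    """X1: ten pulse-amplitude summaries (both channels)."""

    pulse_min_abp: float
    pulse_mean_abp: float
    pulse_deriv_abp: float
    frac_below5_abp: float
    frac_below10_abp: float
    pulse_min_icp: float
    pulse_mean_icp: float
    pulse_deriv_icp: float
    frac_below5_icp: float
    frac_below10_icp: float

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


@dataclass(frozen=True)
class InformativeFeatures:
    """X2: filtered-SD profile plus channel means."""

    sd_abp_60: float
    sd_abp_120: float
    sd_abp_180: float
    sd_abp_240: float
    sd_icp_60: float
    sd_icp_120: float
    sd_icp_180: float
    sd_icp_240: float
    mean_abp: float
    mean_icp: float

    @classmethod
    def names(cls) -> list[str]:
        return [f.name for f in fields(cls)]

    def to_dict(self) -> dict[str, float]:
        return {f.name: getattr(self, f.name) for f in fields(self)}


def _channel_pulse_stats(sys_: np.ndarray, dia: np.ndarray,
                         sample_period_s: float) -> tuple[float, ...] | None:
    d = sys_ - dia
    valid = np.isfinite(d)
    n = d.size
    if n == 0 or valid.mean() < MIN_VALID_FRACTION:
        return None
    dv = d[valid]
    # derivative over consecutive valid pairs only
    pair = valid[1:] & valid[:-1]
    if pair.any():
        deriv = float(np.mean(np.abs(np.diff(d)[pair]))) / sample_period_s
    else:
        deriv = 0.0
    frac5 = float(np.sum(valid & (d < PULSE_THRESHOLDS[0]))) / n
    frac10 = float(np.sum(valid & (d < PULSE_THRESHOLDS[1]))) / n
    return float(np.min(dv)), float(np.mean(dv)), deriv, frac5, frac10


def artifact_features(segment_record: MonitoringRecord) -> ArtifactFeatures | None:
    """X1 for one 24-min slice; None when too few sys/dia samples remain."""
    abp = _channel_pulse_stats(segment_record.abp_sys, segment_record.abp_dia,
                               segment_record.sample_period_s)
    icp = _channel_pulse_stats(segment_record.icp_sys, segment_record.icp_dia,
                               segment_record.sample_period_s)
    if abp is None or icp is None:
        return None
    return ArtifactFeatures(*abp, *icp)


def _moving_average(x: np.ndarray, width_n: int) -> np.ndarray:
    # centered moving average, truncated (shrinking) at the edges, NaN-aware
    return (pd.Series(x)
            .rolling(window=width_n, center=True, min_periods=1)
            .mean()
            .to_numpy())


def informative_features(segment_record: MonitoringRecord) -> InformativeFeatures | None:
    """X2 for one 24-min slice; None when too few mean samples remain."""
    sp = segment_record.sample_period_s
    out: dict[str, float] = {}
    for ch, series in (("abp", segment_record.abp_mean), ("icp", segment_record.icp_mean)):
        valid = np.isfinite(series)
        if series.size == 0 or valid.mean() < MIN_VALID_FRACTION:
            return None
        for w in FILTER_WINDOWS_S:
            filt = _moving_average(series, max(1, int(round(w / sp))))
            out[f"sd_{ch}_{w}"] = float(np.nanstd(filt, ddof=1))
        out[f"mean_{ch}"] = float(np.nanmean(series))
    return InformativeFeatures(**out)


def segment_feature_table(record: MonitoringRecord,
                          segments: list[Segment]) -> pd.DataFrame:
    """X1 and X2 for a list of segments, one row per (window_id, segment_index).

    Rows whose feature vector could not be computed are all-NaN for that
    block; downstream policy treats a missing X1 row as artifact-distorted.
    """
    rows = []
    for seg in segments:
        sl = record.slice(seg.start_s, seg.end_s)
        row: dict[str, float] = {"window_id": seg.window_id,
                                 "segment_index": seg.segment_index}
        x1 = artifact_features(sl)
        row.update(x1.to_dict() if x1 is not None
                   else dict.fromkeys(ArtifactFeatures.names(), np.nan))
        x2 = informative_features(sl)
        row.update(x2.to_dict() if x2 is not None
                   else dict.fromkeys(InformativeFeatures.names(), np.nan))
        rows.append(row)
    return pd.DataFrame(rows).set_index(["window_id", "segment_index"])
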