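"""Sliding 2-h analysis windows and their five 24-min segments.

A 2-h episode is deconstructed into five contiguous 24-min segments; windows
slide by one segment length so a fresh management decision is available
every 24 minutes.  Intervals are half-open ``[start, end)`` and segment
indices are 0-based.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np

from .io import MonitoringRecord, ValidationError

__all__ = [
    "Segment",
    "WINDOW_S",
    "SEGMENT_S",
    "SEGMENTS_PER_WINDOW",
    "window_starts",
    "make_windows",
    "split_window",
]

WINDOW_S = 7200.0
SEGMENT_S = 1440.0
SEGMENTS_PER_WINDOW = 5


@dataclass(frozen=True)
class Segment:
    window_id: str
    segment_index: int
    start_s: float
    end_s: float
    artifact_label: str = "unlabeled"      # Y1
    informative_label: str = "unlabeled"   # Y2

    def __post_init__(self) -> None:
        if not 0 <= self.segment_index < SEGMENTS_PER_WINDOW:
            raise ValidationError("segment_index must lie in 0..4")
        if abs((self.end_s - self.start_s) - SEGMENT_S) > 1e-6:
            raise ValidationError(f"segment must span {SEGMENT_S} s")

    def with_labels(self, artifact_label: str, informative_label: str) -> "Segment":
        return replace(self, artifact_label=artifact_label,
                       informative_label=informative_label)

    @property
    def is_artifact_free(self) -> bool:
        return self.artifact_label == "artifact_free"

    @property
    def is_informative(self) -> bool:
        return self.informative_label == "informative"


def window_starts(duration_s: float, window_s: float = WINDOW_S,
                  step_s: float = SEGMENT_S) -> np.ndarray:
    """Start times of all complete sliding windows; partial tails are dropped."""
    if duration_s < window_s:
        return np.empty(0)
    n = int(np.floor((duration_s - window_s) / step_s)) + 1
    return np.arange(n) * step_s


def make_windows(record: MonitoringRecord, window_s: float = WINDOW_S,
                 step_s: float = SEGMENT_S) -> list[tuple[str, float]]:
    """Enumerate (window_id, start_s) sliding windows over a record."""
    starts = window_starts(record.duration_s, window_s, step_s)
    if starts.size == 0:
        warnings.warn("record shorter than one analysis window", stacklevel=2)
        return []
    return [(f"w{i:04d}", float(s)) for i, s in enumerate(starts)]


def split_window(window_id: str, start_s: float,
                 window_s: float = WINDOW_S) -> list[Segment]:
    """Tile one 2-h window into its five half-open 24-min segments."""
    if abs(window_s - SEGMENTS_PER_WINDOW * SEGMENT_S) > 1e-6:
        raise ValidationError(
            f"window must span {SEGMENTS_PER_WINDOW} x {SEGMENT_S} s")
    return [
        Segment(
            window_id=window_id,
            segment_index=k,
            start_s=start_s + k * SEGMENT_S,
            end_s=start_s + (k + 1) * SEGMENT_S,
        )
        for k in range(SEGMENTS_PER_WINDOW)
    ]
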