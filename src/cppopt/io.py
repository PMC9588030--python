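"""On-disk formats for monitoring records and segment annotations.

Monitoring data travel as plain CSV with one row per sample and the seven
columns ``time_s, abp_mean, abp_sys, abp_dia, icp_mean, icp_sys, icp_dia``
(mmHg, dot decimal, UTF-8, header required).  Missing values are empty cells
on disk and NaN in memory.  Annotations are small CSV/JSON tables keyed by
``(window_id, segment_index)``.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "FormatError",
    "ValidationError",
    "MonitoringRecord",
    "AnnotationTable",
    "read_monitoring_csv",
    "write_monitoring_csv",
    "read_annotations",
    "write_annotations",
    "ARTIFACT_LABELS",
    "INFORMATIVE_LABELS",
]

MONITORING_COLUMNS = (
    "time_s",
    "abp_mean",
    "abp_sys",
    "abp_dia",
    "icp_mean",
    "icp_sys",
    "icp_dia",
)

ARTIFACT_LABELS = ("artifact_free", "artifact_distorted", "unlabeled")
INFORMATIVE_LABELS = ("informative", "noninformative", "unlabeled")

#: absolute tolerance on the constancy of the sampling step, in seconds
_TIME_STEP_TOL = 1e-6
#: tolerance for the sys >= mean >= dia ordering check, in mmHg
_ORDER_TOL = 1e-9


class FormatError(ValueError):
    """A file does not follow the documented on-disk schema."""


class ValidationError(ValueError):
    """Data are schema-conformant but violate a physiological invariant."""


def _as_float_array(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValidationError(f"{name} must be a 1-D series, got shape {arr.shape}")
    return arr


@dataclass
class MonitoringRecord:
    """Time-aligned beat-summary ABP/ICP series for one patient.

    All series share the time base ``t`` (seconds since record start,
    constant step ``sample_period_s``).  Wherever systolic, mean and
    diastolic values are all present the ordering sys >= mean >= dia must
    hold for each channel.
    """

    patient_id: str
    t: np.ndarray
    abp_mean: np.ndarray
    abp_sys: np.ndarray
    abp_dia: np.ndarray
    icp_mean: np.ndarray
    icp_sys: np.ndarray
    icp_dia: np.ndarray
    sample_period_s: float = 1.0

    def __post_init__(self) -> None:
        self.t = _as_float_array(self.t, "t")
        for name in ("abp_mean", "abp_sys", "abp_dia", "icp_mean", "icp_sys", "icp_dia"):
            setattr(self, name, _as_float_array(getattr(self, name), name))
        self.validate()

    # -- invariants ------------------------------------------------------

    def validate(self) -> None:
        if not self.sample_period_s > 0:
            raise ValidationError("sample_period_s must be positive")
        n = self.t.size
        for name in ("abp_mean", "abp_sys", "abp_dia", "icp_mean", "icp_sys", "icp_dia"):
            if getattr(self, name).size != n:
                raise ValidationError(f"series {name} has length "
                                      f"{getattr(self, name).size}, expected {n}")
        if n >= 2:
            dt = np.diff(self.t)
            if np.any(dt <= 0):
                i = int(np.argmax(dt <= 0))
                raise ValidationError(f"time is not strictly increasing at row {i + 1}")
            if np.max(np.abs(dt - self.sample_period_s)) > _TIME_STEP_TOL:
                raise ValidationError(
                    "time step is not constant at "
                    f"{self.sample_period_s} s (tolerance {_TIME_STEP_TOL} s)")
        for ch in ("abp", "icp"):
            sys_, mean_, dia_ = (getattr(self, f"{ch}_{p}") for p in ("sys", "mean", "dia"))
            present = np.isfinite(sys_) & np.isfinite(mean_) & np.isfinite(dia_)
            bad = present & ((sys_ < mean_ - _ORDER_TOL) | (mean_ < dia_ - _ORDER_TOL))
            if np.any(bad):
                rows = np.flatnonzero(bad)
                raise ValidationError(
                    f"{ch}: sys >= mean >= dia violated at rows {rows[:10].tolist()}"
                    + ("..." if rows.size > 10 else ""))

    # -- conveniences ----------------------------------------------------

    @property
    def n_samples(self) -> int:
        return self.t.size

    @property
    def duration_s(self) -> float:
        return self.n_samples * self.sample_period_s

    def slice(self, start_s: float, end_s: float) -> "MonitoringRecord":
        """Half-open time slice [start_s, end_s) relative to the record start."""
        t0 = self.t[0]
        i0 = int(np.searchsorted(self.t, t0 + start_s - _TIME_STEP_TOL, side="left"))
        i1 = int(np.searchsorted(self.t, t0 + end_s - _TIME_STEP_TOL, side="left"))
        return replace(
            self,
            t=self.t[i0:i1],
            abp_mean=self.abp_mean[i0:i1],
            abp_sys=self.abp_sys[i0:i1],
            abp_dia=self.abp_dia[i0:i1],
            icp_mean=self.icp_mean[i0:i1],
            icp_sys=self.icp_sys[i0:i1],
            icp_dia=self.icp_dia[i0:i1],
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_s": self.t,
                "abp_mean": self.abp_mean,
                "abp_sys": self.abp_sys,
                "abp_dia": self.abp_dia,
                "icp_mean": self.icp_mean,
                "icp_sys": self.icp_sys,
                "icp_dia": self.icp_dia,
            }
        )


def read_monitoring_csv(
    path, sample_period_s: float = 1.0, patient_id: str | None = None
) -> MonitoringRecord:
    """Read a monitoring CSV into a validated :class:`MonitoringRecord`.

    Empty cells become NaN.  The time column must be strictly increasing
    with a constant step equal to ``sample_period_s`` (to within 1e-6 s);
    anything else is rejected rather than silently resampled.
    """
    path = Path(path)
    df = pd.read_csv(path)
    for col in MONITORING_COLUMNS:
        if col not in df.columns:
            raise FormatError(f"monitoring CSV {path.name}: missing column {col!r}")
    return MonitoringRecord(
        patient_id=patient_id if patient_id is not None else path.stem,
        t=df["time_s"].to_numpy(float),
        abp_mean=df["abp_mean"].to_numpy(float),
        abp_sys=df["abp_sys"].to_numpy(float),
        abp_dia=df["abp_dia"].to_numpy(float),
        icp_mean=df["icp_mean"].to_numpy(float),
        icp_sys=df["icp_sys"].to_numpy(float),
        icp_dia=df["icp_dia"].to_numpy(float),
        sample_period_s=sample_period_s,
    )


def write_monitoring_csv(record: MonitoringRecord, path) -> None:
    record.to_frame().to_csv(path, index=False, float_format="%.17g")


# ---------------------------------------------------------------------------
# annotations


@dataclass
class AnnotationTable:
    """Per-segment artifact (Y1) and informative (Y2) labels.

    One row per ``(window_id, segment_index)``; segment_index runs 0..4
    within a 2-h window.  Label vocabularies are closed.
    """

    df: pd.DataFrame = field(default_factory=lambda: AnnotationTable.empty_frame())

    COLUMNS = ("window_id", "segment_index", "artifact_label", "informative_label")

    @staticmethod
    def empty_frame() -> pd.DataFrame:
        return pd.DataFrame(
            {"window_id": pd.Series(dtype=str),
             "segment_index": pd.Series(dtype=int),
             "artifact_label": pd.Series(dtype=str),
             "informative_label": pd.Series(dtype=str)})

    def __post_init__(self) -> None:
        df = self.df.copy()
        for col in self.COLUMNS:
            if col not in df.columns:
                raise FormatError(f"annotation table: missing column {col!r}")
        df = df[list(self.COLUMNS)]
        df["window_id"] = df["window_id"].astype(str)
        df["segment_index"] = df["segment_index"].astype(int)
        if len(df):
            if df["segment_index"].min() < 0 or df["segment_index"].max() > 4:
                raise ValidationError("segment_index must lie in 0..4")
            for col, vocab in (("artifact_label", ARTIFACT_LABELS),
                               ("informative_label", INFORMATIVE_LABELS)):
                bad = set(df[col]) - set(vocab)
                if bad:
                    raise ValidationError(f"{col}: unknown labels {sorted(bad)}")
            dup = df.duplicated(subset=["window_id", "segment_index"])
            if dup.any():
                keys = df.loc[dup, ["window_id", "segment_index"]].to_records(index=False)
                raise ValidationError(f"duplicate (window_id, segment_index): {list(keys)[:5]}")
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def lookup(self, window_id: str, segment_index: int) -> tuple[str, str]:
        """Return (artifact_label, informative_label); 'unlabeled' if absent."""
        m = (self.df["window_id"] == str(window_id)) & (
            self.df["segment_index"] == int(segment_index))
        if not m.any():
            return "unlabeled", "unlabeled"
        row = self.df.loc[m].iloc[0]
        return str(row["artifact_label"]), str(row["informative_label"])


def read_annotations(path) -> AnnotationTable:
    """Read an annotation table from CSV or JSON (by file suffix)."""
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path) as fh:
            rows = json.load(fh)
        if not isinstance(rows, list):
            raise FormatError("annotation JSON must be a list of row objects")
        df = pd.DataFrame(rows, columns=list(AnnotationTable.COLUMNS))
    else:
        df = pd.read_csv(path, dtype={"window_id": str})
    return AnnotationTable(df)


def write_annotations(table: AnnotationTable, path) -> None:
    path = Path(path)
    if path.suffix.lower() == ".json":
        with open(path, "w") as fh:
            json.dump(table.df.to_dict(orient="records"), fh, indent=1)
    else:
        table.df.to_csv(path, index=False)
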