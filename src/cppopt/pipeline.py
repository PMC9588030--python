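"""End-to-end workflow: record -> PRx -> segments -> classifiers -> fits ->
management decisions -> yield.

``run_pipeline`` is the programmatic equivalent of the full analysis chain:
compute PRx, slide 2-h windows in 24-min steps, label every 24-min slot as
artifact-free/distorted and informative/noninformative (by trained SVMs,
by a provided annotation table, or -- with ``use_ml=False`` -- by assuming
every segment is clean and informative), run the R^2-driven segment
selection and the triple-axis U-shape fits per window, classify the window
into one of the five clinical situations and aggregate the yield report.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import AnnotationTable, MonitoringRecord
from .prx import PRxParams, PRxSeries, compute_prx
from .segments import SEGMENT_S, Segment, make_windows, split_window
from .features import (ArtifactFeatures, InformativeFeatures, segment_feature_table,
                       artifact_features, informative_features)
from .svm import TrainedModel, GridSearchResult, grid_search_train, predict
from .ushape import UShapeFit, select_segments
from .decide import ManagementDecision, YieldReport, classify_window, yield_report
from .simulate import GroundTruth

__all__ = [
    "RunConfig",
    "PipelineResult",
    "run_pipeline",
    "labeled_segment_features",
    "train_segment_classifiers",
    "window_feature_table",
]


@dataclass(frozen=True)
class RunConfig:
    """All tunables of one pipeline run, serializable to YAML/JSON."""

    prx: PRxParams = field(default_factory=PRxParams)
    window_s: float = 7200.0
    step_s: float = 1440.0
    bin_width: float = 5.0
    min_count: int = 5
    threshold: float = 0.3
    min_r2: float = 0.0
    seed: int = 0

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "prx" in d and isinstance(d["prx"], dict):
            d["prx"] = PRxParams(**d["prx"])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "RunConfig":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        return cls.from_dict(d)


@dataclass
class PipelineResult:
    windows: list[tuple[str, float]]
    segments: dict[str, list[Segment]]
    fits: dict[str, dict[str, UShapeFit | None]]
    decisions: list[ManagementDecision]
    yields: YieldReport
    prx: PRxSeries
    config: RunConfig

    def decisions_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [{"window_id": d.window_id, **d.flags(),
              "primary_situation": d.primary_situation,
              "missing_data": d.missing_data} for d in self.decisions])

    def fits_frame(self) -> pd.DataFrame:
        rows = []
        for wid, per_axis in self.fits.items():
            for axis, fit in per_axis.items():
                row = {"window_id": wid, "axis": axis}
                if fit is None:
                    row.update({"valid": False, "a": np.nan, "b": np.nan,
                                "c0": np.nan, "r_squared": np.nan,
                                "opt_value": None, "llca": None, "ulca": None,
                                "n_bins": 0, "chosen_segments": None})
                else:
                    row.update(fit.to_dict())
                    row.pop("axis")
                    row["axis"] = axis
                rows.append(row)
        return pd.DataFrame(rows)

    def save(self, outdir) -> None:
        """Write fits.csv, decisions.csv, yield.json and a run manifest."""
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        self.fits_frame().to_csv(outdir / "fits.csv", index=False)
        self.decisions_frame().to_csv(outdir / "decisions.csv", index=False)
        self.yields.to_json(outdir / "yield.json")
        cfg = self.config.to_dict()
        manifest = {
            "config": cfg,
            "config_sha256": hashlib.sha256(
                json.dumps(cfg, sort_keys=True).encode()).hexdigest(),
            "seed": self.config.seed,
            "n_windows": len(self.windows),
        }
        with open(outdir / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=1)


def _slot_labels_ml(
    record: MonitoringRecord,
    n_slots: int,
    artifact_model: TrainedModel | None,
    informative_model: TrainedModel | None,
) -> pd.DataFrame:
    """Predict Y1/Y2 per absolute 24-min slot with the trained models.

    Slots whose X1 vector is missing are artifact-distorted by policy;
    missing X2 maps to noninformative.
    """
    rows = []
    for slot in range(n_slots):
        sl = record.slice(slot * SEGMENT_S, (slot + 1) * SEGMENT_S)
        x1 = artifact_features(sl)
        x2 = informative_features(sl)
        rows.append((x1, x2))

    art = []
    if artifact_model is None:
        art = ["artifact_free"] * n_slots
    else:
        have = [i for i, (x1, _) in enumerate(rows) if x1 is not None]
        art = ["artifact_distorted"] * n_slots
        if have:
            X1 = pd.DataFrame([rows[i][0].to_dict() for i in have])
            labels, _ = predict(artifact_model, X1)
            for i, lab in zip(have, labels):
                art[i] = "artifact_free" if lab == 1 else "artifact_distorted"

    info = []
    if informative_model is None:
        info = ["informative"] * n_slots
    else:
        have = [i for i, (_, x2) in enumerate(rows) if x2 is not None]
        info = ["noninformative"] * n_slots
        if have:
            X2 = pd.DataFrame([rows[i][1].to_dict() for i in have])
            labels, _ = predict(informative_model, X2)
            for i, lab in zip(have, labels):
                info[i] = "informative" if lab == 1 else "noninformative"

    return pd.DataFrame({"slot": np.arange(n_slots),
                         "artifact_label": art, "informative_label": info})


def run_pipeline(
    record: MonitoringRecord,
    *,
    artifact_model: TrainedModel | None = None,
    informative_model: TrainedModel | None = None,
    annotations: AnnotationTable | None = None,
    slot_labels: pd.DataFrame | None = None,
    use_ml: bool = True,
    config: RunConfig = RunConfig(),
) -> PipelineResult:
    """Run the full analysis chain over one monitoring record.

    Label sources, in order of precedence: an explicit per-slot label frame
    (``slot_labels``, e.g. simulator ground truth), a per-(window, segment)
    ``annotations`` table, trained models when ``use_ml`` is true, else the
    no-ML fallback that force-includes every segment as clean and
    informative.
    """
    prx_series = compute_prx(record, config.prx)
    windows = make_windows(record, config.window_s, config.step_s)

    n_slots = int(record.duration_s // SEGMENT_S)
    slot_frame: pd.DataFrame | None = slot_labels
    if slot_frame is None and annotations is None:
        if use_ml:
            slot_frame = _slot_labels_ml(record, n_slots, artifact_model,
                                         informative_model)
        else:
            slot_frame = pd.DataFrame({
                "slot": np.arange(n_slots),
                "artifact_label": "artifact_free",
                "informative_label": "informative"})
    if slot_frame is not None:
        slot_frame = slot_frame.set_index("slot")

    segments_by_window: dict[str, list[Segment]] = {}
    fits: dict[str, dict[str, UShapeFit | None]] = {}
    decisions: list[ManagementDecision] = []

    for wid, start in windows:
        segs = split_window(wid, start, config.window_s)
        labelled = []
        for seg in segs:
            if slot_frame is not None:
                slot = int(round(seg.start_s / SEGMENT_S))
                row = slot_frame.loc[slot]
                labelled.append(seg.with_labels(str(row["artifact_label"]),
                                                str(row["informative_label"])))
            else:
                art, info = annotations.lookup(wid, seg.segment_index)
                labelled.append(seg.with_labels(art, info))
        segments_by_window[wid] = labelled

        prx_win = prx_series.window(start, start + config.window_s)
        per_axis: dict[str, UShapeFit | None] = {}
        for axis in ("cpp", "abp", "icp"):
            _, fit = select_segments(
                labelled, prx_series, axis,
                bin_width=config.bin_width, min_count=config.min_count,
                threshold=config.threshold, min_r2=config.min_r2)
            per_axis[axis] = fit
        fits[wid] = per_axis
        decisions.append(classify_window(
            wid, per_axis, prx_win,
            critical_threshold=config.threshold,
            bin_width=config.bin_width, min_count=config.min_count))

    return PipelineResult(
        windows=windows,
        segments=segments_by_window,
        fits=fits,
        decisions=decisions,
        yields=yield_report(decisions, fits) if decisions else YieldReport({}, 0),
        prx=prx_series,
        config=config,
    )


# ---------------------------------------------------------------------------
# training helpers


def labeled_segment_features(record: MonitoringRecord, truth: GroundTruth,
                             artifact_overlap: float = 0.1) -> pd.DataFrame:
    """Per-slot X1+X2 features with ground-truth Y1/Y2 labels.

    Slots with a missing X1 or X2 vector are dropped (they are excluded
    from training; at prediction time the missing-data policy applies).
    Y1 = 1 for artifact-free, Y2 = 1 for informative, matching the label
    conventions of the artifact and informative models.
    """
    labels = truth.slot_labels(artifact_overlap)
    n_slots = len(labels)
    rows = []
    for slot in range(n_slots):
        sl = record.slice(slot * SEGMENT_S, (slot + 1) * SEGMENT_S)
        x1, x2 = artifact_features(sl), informative_features(sl)
        if x1 is None or x2 is None:
            continue
        row = {"slot": slot, **x1.to_dict(), **x2.to_dict()}
        row["y1"] = int(labels.loc[slot, "artifact_label"] == "artifact_free")
        row["y2"] = int(labels.loc[slot, "informative_label"] == "informative")
        rows.append(row)
    return pd.DataFrame(rows).set_index("slot")


def train_segment_classifiers(
    features: pd.DataFrame, seed: int = 0
) -> tuple[tuple[TrainedModel, GridSearchResult], tuple[TrainedModel, GridSearchResult]]:
    """Grid-search-train the artifact (X1/Y1) and informative (X2/Y2) models."""
    x1_cols = ArtifactFeatures.names()
    x2_cols = InformativeFeatures.names()
    artifact = grid_search_train(features[x1_cols], features["y1"], seed=seed)
    informative = grid_search_train(features[x2_cols], features["y2"], seed=seed + 1)
    return artifact, informative


def window_feature_table(result: PipelineResult,
                         record: MonitoringRecord) -> pd.DataFrame:
    """Per-window features for the management-recognition models.

    Mean X2 features over the window's five segments, concatenated with PRx
    summaries (mean, 10th/90th percentile, CPP range).  Windows without a
    single finite PRx sample are dropped.
    """
    x2_cols = InformativeFeatures.names()
    rows = []
    for wid, start in result.windows:
        segs = result.segments[wid]
        x2s = []
        for seg in segs:
            x2 = informative_features(record.slice(seg.start_s, seg.end_s))
            if x2 is not None:
                x2s.append(list(x2.to_dict().values()))
        if not x2s:
            continue
        prx_win = result.prx.window(start, start + result.config.window_s)
        prx = prx_win.prx[np.isfinite(prx_win.prx)]
        cpp = prx_win.cpp_mean[np.isfinite(prx_win.cpp_mean)]
        if prx.size == 0 or cpp.size == 0:
            continue
        row = {"window_id": wid}
        row.update(dict(zip(x2_cols, np.mean(x2s, axis=0))))
        row.update({
            "prx_mean": float(np.mean(prx)),
            "prx_p10": float(np.percentile(prx, 10)),
            "prx_p90": float(np.percentile(prx, 90)),
            "cpp_range": float(cpp.max() - cpp.min()),
        })
        rows.append(row)
    return pd.DataFrame(rows).set_index("window_id")
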