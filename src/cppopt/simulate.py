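"""Synthetic multimodal neuromonitoring with a known autoregulation curve.

The generator emulates the raw material of pressure-reactivity monitoring:

* a slowly drifting mean ABP whose excursions let CPP sweep a chosen range,
* slow vasogenic B-waves (0.5-2 cycles/min) that are present only in
  "informative" 24-min segments,
* an ABP->ICP coupling whose strength and sign follow a ground-truth
  autoregulation parabola rho(CPP) = clip(a_true*(CPP - x_opt_true)^2 +
  c_true, -0.99, 0.99), so the expected PRx at a given CPP is known in
  closed form,
* pulse components (sys/dia = mean +/- pulse_amp/2) and injected artifact
  episodes (damped pulse amplitude, or dropouts that freeze all values).

The coupling is realized by correlation injection at the 10-s-bin scale:
within each 5-min block the standardized slow ABP component z is mixed with
unit white noise eps as ``icp_slow = rho_eff*z*s + sqrt(1-rho_eff^2)*eps*s``.
The injected correlation is gated by the actual slow-wave amplitude,
``rho_eff = rho * min(1, s_block/s_ref)`` with ``s_ref = bwave_amp/sqrt(2)``:
at the design B-wave amplitude the expectation is exactly rho(CPP), while
segments without B-waves yield a weak, noisy PRx - the amplitude ambiguity
the informative-segment classifier exists to resolve.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .io import MonitoringRecord, ValidationError

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "simulate_monitoring",
    "truth_prx_expectation",
    "sweep_config",
]

SEGMENT_S = 1440.0  # 24 min
_BIN_S = 10.0
_BLOCK_BINS = 30  # 5-min correlation-injection blocks

PRX_CLIP = 0.99
#: minimum B-wave amplitude (mmHg) for a segment to count as informative
_BWAVE_MIN_AMP = 1.0


@dataclass
class SimulationConfig:
    """Everything the generator needs; ``seed`` fixes the full output.

    ``abp_drift`` is a piecewise-linear set of (time_s, mmHg) breakpoints
    added to ``abp_baseline``; the ground-truth curve is the parabola
    ``rho(CPP) = a_true*(CPP - x_opt_true)^2 + c_true`` clipped to
    [-0.99, 0.99].
    """

    duration_s: float = 21600.0
    seed: int = 0
    abp_baseline: float = 95.0
    abp_drift: tuple[tuple[float, float], ...] = ()
    bwave_amp: float = 5.0
    bwave_period_s: tuple[float, float] = (30.0, 120.0)
    bwave_on_fraction: float = 0.75
    pulse_amp_abp: float = 40.0
    pulse_amp_icp: float = 8.0
    pulse_jitter_sd: float = 1.0
    a_true: float = 0.002
    x_opt_true: float = 80.0
    c_true: float = -0.2
    icp_baseline: float = 15.0
    icp_slow_sd: float = 2.0
    noise_sd: float = 1.0
    artifact_rate_per_h: float = 0.25
    artifact_duration_s: tuple[float, float] = (60.0, 600.0)
    artifact_kind: str = "mixed"  # damped_pulse | dropout | mixed

    def __post_init__(self) -> None:
        if self.duration_s < 7200:
            raise ValidationError("duration_s must cover at least one 2-h window")
        if not self.a_true > 0:
            raise ValidationError("a_true must be positive (U-shape opens upward)")
        if not (-1.0 <= self.c_true < 0.3):
            raise ValidationError(
                "c_true must lie in [-1, 0.3); at or above the +0.3 threshold the "
                "ground-truth autoregulation limits are undefined")
        if not (0.0 <= self.bwave_on_fraction <= 1.0):
            raise ValidationError("bwave_on_fraction must lie in [0, 1]")
        lo, hi = self.bwave_period_s
        if not (0 < lo <= hi):
            raise ValidationError("bwave_period_s must be an increasing positive range")
        if self.artifact_kind not in ("damped_pulse", "dropout", "mixed"):
            raise ValidationError(f"unknown artifact_kind {self.artifact_kind!r}")

    # ground-truth limits: parabola crosses the +0.3 threshold at
    # x_opt_true -/+ sqrt((0.3 - c_true)/a_true)
    @property
    def llca_true(self) -> float:
        return self.x_opt_true - math.sqrt((0.3 - self.c_true) / self.a_true)

    @property
    def ulca_true(self) -> float:
        return self.x_opt_true + math.sqrt((0.3 - self.c_true) / self.a_true)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["abp_drift"] = [list(bp) for bp in self.abp_drift]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        d["abp_drift"] = tuple((float(t), float(v)) for t, v in d.get("abp_drift", ()))
        for key in ("bwave_period_s", "artifact_duration_s"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def load(cls, path) -> "SimulationConfig":
        path = Path(path)
        with open(path) as fh:
            d = json.load(fh) if path.suffix.lower() == ".json" else yaml.safe_load(fh)
        return cls.from_dict(d)

    def save(self, path) -> None:
        path = Path(path)
        with open(path, "w") as fh:
            if path.suffix.lower() == ".json":
                json.dump(self.to_dict(), fh, indent=1)
            else:
                yaml.safe_dump(self.to_dict(), fh)


def sweep_config(
    duration_s: float,
    seed: int = 0,
    cpp_min: float = 55.0,
    cpp_max: float = 105.0,
    sweep_period_s: float = 7200.0,
    rise_fraction: float = 0.8,
    **overrides,
) -> SimulationConfig:
    """Config whose CPP sweeps [cpp_min, cpp_max] as a sawtooth.

    The sweep rises slowly (``rise_fraction`` of the period, a
    vasopressor-titration-like ~31 mmHg/h at the defaults) and relaxes back
    quickly, with breakpoints aligned to 24-min segment boundaries.  With
    the period equal to the 2-h analysis window every window covers the full
    CPP range, the regime in which a complete U-shape is recoverable; a
    symmetric triangle of longer period would leave windows centered on a
    sweep extreme seeing a single flank of the curve.
    """
    icp_baseline = overrides.get("icp_baseline", SimulationConfig.icp_baseline)
    mid = 0.5 * (cpp_min + cpp_max)
    half = 0.5 * (cpp_max - cpp_min)
    bps: list[tuple[float, float]] = []
    t = 0.0
    while t <= duration_s + sweep_period_s:
        bps.append((t, -half))
        bps.append((t + rise_fraction * sweep_period_s, half))
        t += sweep_period_s
    return SimulationConfig(
        duration_s=duration_s,
        seed=seed,
        abp_baseline=icp_baseline + mid,
        abp_drift=tuple(bps),
        **overrides,
    )


@dataclass
class GroundTruth:
    """Per-sample artifact flags and per-segment informative flags."""

    artifact: np.ndarray           # bool per sample
    informative: np.ndarray        # bool per 24-min segment slot
    x_opt_true: float
    llca_true: float
    ulca_true: float

    def __post_init__(self) -> None:
        if not (self.llca_true < self.x_opt_true < self.ulca_true):
            raise ValidationError("ground-truth limits must bracket the optimum")

    def slot_labels(self, artifact_overlap: float = 0.1) -> pd.DataFrame:
        """Per-24-min-slot Y1/Y2 labels derived from the ground truth.

        A slot is labelled artifact-distorted when artifacts cover at least
        ``artifact_overlap`` of its samples.
        """
        n_slots = self.informative.size
        per_slot = self.artifact[: n_slots * int(SEGMENT_S)].reshape(n_slots, -1)
        distorted = per_slot.mean(axis=1) >= artifact_overlap
        return pd.DataFrame(
            {
                "slot": np.arange(n_slots),
                "artifact_label": np.where(distorted, "artifact_distorted", "artifact_free"),
                "informative_label": np.where(self.informative, "informative", "noninformative"),
            }
        )

    def to_json(self, path) -> None:
        flag = np.asarray(self.artifact, dtype=bool)
        edges = np.flatnonzero(np.diff(np.concatenate(([False], flag, [False]))))
        intervals = edges.reshape(-1, 2).tolist()  # [start, end) sample indices
        with open(path, "w") as fh:
            json.dump(
                {
                    "artifact_intervals": intervals,
                    "informative_segments": np.asarray(self.informative, bool).astype(int).tolist(),
                    "x_opt_true": self.x_opt_true,
                    "llca_true": self.llca_true,
                    "ulca_true": self.ulca_true,
                },
                fh,
            )


def truth_prx_expectation(cpp, config: SimulationConfig):
    """Expected PRx at a given CPP under the ground-truth parabola."""
    cpp = np.asarray(cpp, dtype=float)
    rho = config.a_true * (cpp - config.x_opt_true) ** 2 + config.c_true
    return np.clip(rho, -PRX_CLIP, PRX_CLIP)


def _bwave_component(config: SimulationConfig, informative: np.ndarray,
                     rng: np.random.Generator, n: int) -> np.ndarray:
    """Sinusoidal B-waves, per segment, only where the segment is informative."""
    w = np.zeros(n)
    seg_len = int(SEGMENT_S)
    lo, hi = config.bwave_period_s
    for s, on in enumerate(informative):
        period = rng.uniform(lo, hi)
        phase = rng.uniform(0, 2 * math.pi)
        if not on:
            continue
        i0, i1 = s * seg_len, min((s + 1) * seg_len, n)
        tt = np.arange(i0, i1, dtype=float)
        w[i0:i1] = config.bwave_amp * np.sin(2 * math.pi * tt / period + phase)
    return w


def _icp_slow_component(config: SimulationConfig, abp_slow_dev: np.ndarray,
                        cpp_nominal: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Correlation-injected slow ICP component, built on 10-s bins.

    ``abp_slow_dev`` is the noise-free slow ABP component (B-wave + drift)
    and ``cpp_nominal`` the noise-free CPP proxy used to evaluate rho.
    """
    n = abp_slow_dev.size
    bin_n = int(_BIN_S)
    n_bins = n // bin_n
    w_bins = abp_slow_dev[: n_bins * bin_n].reshape(n_bins, bin_n).mean(axis=1)
    cpp_bins = cpp_nominal[: n_bins * bin_n].reshape(n_bins, bin_n).mean(axis=1)
    s_ref = config.bwave_amp / math.sqrt(2.0)
    s_icp = config.icp_slow_sd
    out_bins = np.zeros(n_bins)
    eps = rng.standard_normal(n_bins)
    for b0 in range(0, n_bins, _BLOCK_BINS):
        b1 = min(b0 + _BLOCK_BINS, n_bins)
        w = w_bins[b0:b1]
        sd = float(np.std(w))
        rho = float(np.clip(
            config.a_true * (float(np.mean(cpp_bins[b0:b1])) - config.x_opt_true) ** 2
            + config.c_true, -PRX_CLIP, PRX_CLIP))
        if sd > 0:
            gate = 1.0 if s_ref == 0 else min(1.0, sd / s_ref)
            rho_eff = rho * gate
            z = (w - w.mean()) / sd
        else:
            rho_eff = 0.0
            z = np.zeros_like(w)
        out_bins[b0:b1] = (rho_eff * z + math.sqrt(max(0.0, 1 - rho_eff ** 2))
                           * eps[b0:b1]) * s_icp
    # step-function upsampling keeps the 10-s bin means exactly as constructed
    out = np.repeat(out_bins, bin_n)
    if out.size < n:
        out = np.concatenate([out, np.full(n - out.size, out_bins[-1] if n_bins else 0.0)])
    return out


def _inject_artifacts(config: SimulationConfig, rng: np.random.Generator,
                      channels: dict[str, np.ndarray], n: int) -> np.ndarray:
    flag = np.zeros(n, dtype=bool)
    n_events = rng.poisson(config.artifact_rate_per_h * config.duration_s / 3600.0)
    lo, hi = config.artifact_duration_s
    for _ in range(n_events):
        dur = int(rng.uniform(lo, hi))
        start = int(rng.integers(0, max(1, n - dur)))
        end = min(n, start + dur)
        kind = config.artifact_kind
        if kind == "mixed":
            kind = "damped_pulse" if rng.random() < 0.5 else "dropout"
        if kind == "damped_pulse":
            # pulse amplitude collapses exponentially to a ~1 mmHg residual
            tt = np.arange(end - start, dtype=float)
            for ch in ("abp", "icp"):
                full = channels[f"{ch}_sys"][start:end] - channels[f"{ch}_dia"][start:end]
                amp = np.maximum(full * np.exp(-tt / 10.0), 1.0)
                mid = channels[f"{ch}_mean"][start:end]
                channels[f"{ch}_sys"][start:end] = mid + amp / 2
                channels[f"{ch}_dia"][start:end] = mid - amp / 2
        else:  # dropout: everything frozen at the onset value
            for name, series in channels.items():
                series[start:end] = series[start]
        flag[start:end] = True
    return flag


def simulate_monitoring(config: SimulationConfig) -> tuple[MonitoringRecord, GroundTruth]:
    """Generate one synthetic monitoring record plus its ground truth.

    Deterministic for a given config (the seed drives a private generator).
    """
    rng = np.random.default_rng(config.seed)
    n = int(round(config.duration_s))  # canonical 1 Hz
    n_slots = n // int(SEGMENT_S)
    if n_slots == 0:
        raise ValidationError("duration too short for a single 24-min segment")

    # a segment only counts as informative if it actually carries B-waves of
    # at least the minimum detectable amplitude
    informative = (rng.random(n_slots) < config.bwave_on_fraction) & (
        config.bwave_amp >= _BWAVE_MIN_AMP)
    t = np.arange(n, dtype=float)
    if config.abp_drift:
        bp_t = np.array([bp[0] for bp in config.abp_drift])
        bp_v = np.array([bp[1] for bp in config.abp_drift])
        drift = np.interp(t, bp_t, bp_v)
    else:
        drift = np.zeros(n)

    bwave = _bwave_component(config, informative, rng, n)
    abp_slow = config.abp_baseline + drift + bwave
    icp_slow = _icp_slow_component(
        config, bwave + drift, abp_slow - config.icp_baseline, rng)

    abp_mean = abp_slow + rng.normal(0.0, config.noise_sd, n)
    icp_mean = config.icp_baseline + icp_slow

    # beat-to-beat pulse-pressure variability; without it a frozen (dropout)
    # line would be indistinguishable from a clean one in the pulse features
    amp_abp = np.clip(config.pulse_amp_abp
                      + rng.normal(0.0, config.pulse_jitter_sd, n), 0.5, None)
    amp_icp = np.clip(config.pulse_amp_icp
                      + rng.normal(0.0, config.pulse_jitter_sd, n), 0.5, None)
    channels = {
        "abp_mean": abp_mean,
        "abp_sys": abp_mean + amp_abp / 2,
        "abp_dia": abp_mean - amp_abp / 2,
        "icp_mean": icp_mean,
        "icp_sys": icp_mean + amp_icp / 2,
        "icp_dia": icp_mean - amp_icp / 2,
    }
    artifact = _inject_artifacts(config, rng, channels, n)

    record = MonitoringRecord(
        patient_id=f"sim{config.seed:05d}",
        t=t,
        sample_period_s=1.0,
        **channels,
    )
    truth = GroundTruth(
        artifact=artifact,
        informative=informative,
        x_opt_true=config.x_opt_true,
        llca_true=config.llca_true,
        ulca_true=config.ulca_true,
    )
    return record, truth
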