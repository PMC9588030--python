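"""Per-window clinical-situation classification and the yield report.

Each 2-h window is mapped onto five non-exclusive clinical situations:

* critical -- mean PRx exceeds +0.3 in every observed CPP bin: autoregulation
  is globally exhausted and immediate intervention is required;
* intact -- the window mean PRx is negative: no specific treatment needed;
* cpp_guided / abp_guided -- the U-shape (optimum or either CA limit) exists
  on that axis, so that axis can steer management;
* icp_guided -- an upper CA limit exists on the ICP axis.

A single primary situation is picked by the precedence
critical > intact > cpp > abp > icp > none; all flags are kept so nothing
is lost by the ordering.  The yield report is the fraction of windows (of
all windows, i.e. of the full monitoring time) in which each identification
category succeeded.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .prx import PRxSeries
from .ushape import UShapeFit, bin_prx

__all__ = ["ManagementDecision", "YieldReport", "classify_window", "yield_report",
           "YIELD_CATEGORIES"]

PRECEDENCE = ("critical", "intact", "cpp_guided", "abp_guided", "icp_guided")

YIELD_CATEGORIES = (
    "cppopt",            # CPPopt identified
    "abpopt",            # ABPopt identified
    "icp_ulca",          # ULCA identified on the ICP axis
    "cpp_opt_or_limits",
    "abp_opt_or_limits",
    "abp_or_icp",        # ABP (opt or limits) or ICP (ULCA)
    "cpp_or_abp",
    "any_guidance",      # CPP or ABP (opt or limits) or ICP (ULCA)
    "intact",
    "critical",
)


@dataclass(frozen=True)
class ManagementDecision:
    window_id: str
    cpp_guided: bool
    abp_guided: bool
    icp_guided: bool
    intact: bool
    critical: bool
    primary_situation: str
    missing_data: bool = False

    def flags(self) -> dict[str, bool]:
        return {name: getattr(self, name) for name in PRECEDENCE}


def classify_window(
    window_id: str,
    fits: Mapping[str, UShapeFit | None],
    prx_window: PRxSeries,
    *,
    critical_threshold: float = 0.3,
    bin_width: float = 5.0,
    min_count: int = 5,
    min_critical_bins: int = 3,
) -> ManagementDecision:
    """Classify one 2-h window from its triple-axis fits and PRx samples."""
    prx = prx_window.prx[np.isfinite(prx_window.prx)]
    if prx.size == 0:
        return ManagementDecision(window_id, False, False, False, False, False,
                                  "none", missing_data=True)

    cpp_bins = bin_prx(prx_window, "cpp", bin_width, min_count)
    critical = bool(cpp_bins.centers.size >= min_critical_bins
                    and np.all(cpp_bins.means > critical_threshold))
    intact = bool(np.mean(prx) < 0)

    def _guided(axis: str) -> bool:
        fit = fits.get(axis)
        return bool(fit is not None and fit.has_target)

    flags = {
        "critical": critical,
        "intact": intact,
        "cpp_guided": _guided("cpp"),
        "abp_guided": _guided("abp"),
        "icp_guided": _guided("icp"),
    }
    primary = next((name for name in PRECEDENCE if flags[name]), "none")
    return ManagementDecision(
        window_id=window_id,
        cpp_guided=flags["cpp_guided"],
        abp_guided=flags["abp_guided"],
        icp_guided=flags["icp_guided"],
        intact=flags["intact"],
        critical=flags["critical"],
        primary_situation=primary,
    )


@dataclass
class YieldReport:
    """Percentage of 2-h windows in each identification category."""

    percentages: dict[str, float]
    n_windows: int

    def __getitem__(self, key: str) -> float:
        return self.percentages[key]

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump({"n_windows": self.n_windows, **self.percentages}, fh, indent=1)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"category": list(self.percentages),
             "percent": list(self.percentages.values())})


def yield_report(
    decisions: Sequence[ManagementDecision],
    fits_by_window: Mapping[str, Mapping[str, UShapeFit | None]],
) -> YieldReport:
    """Aggregate per-window identification into percentage-of-time yield.

    The denominator is all windows, including those with missing data, so a
    category's percentage is a fraction of the full monitoring time.
    """
    if not decisions:
        raise ValueError("yield report needs at least one window")
    counts = dict.fromkeys(YIELD_CATEGORIES, 0)
    for dec in decisions:
        fits = fits_by_window.get(dec.window_id, {})

        def _get(axis: str, attr: str):
            fit = fits.get(axis)
            return getattr(fit, attr, None) if fit is not None else None

        cppopt = _get("cpp", "opt_value") is not None
        abpopt = _get("abp", "opt_value") is not None
        icp_ulca = _get("icp", "ulca") is not None
        cpp_any = cppopt or _get("cpp", "llca") is not None or _get("cpp", "ulca") is not None
        abp_any = abpopt or _get("abp", "llca") is not None or _get("abp", "ulca") is not None

        row = {
            "cppopt": cppopt,
            "abpopt": abpopt,
            "icp_ulca": icp_ulca,
            "cpp_opt_or_limits": cpp_any,
            "abp_opt_or_limits": abp_any,
            "abp_or_icp": abp_any or icp_ulca,
            "cpp_or_abp": cpp_any or abp_any,
            "any_guidance": cpp_any or abp_any or icp_ulca,
            "intact": dec.intact,
            "critical": dec.critical,
        }
        for key, hit in row.items():
            counts[key] += int(hit)
    n = len(decisions)
    return YieldReport(
        percentages={k: 100.0 * v / n for k, v in counts.items()},
        n_windows=n,
    )
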