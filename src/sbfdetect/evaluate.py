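"""Counting-protocol evaluation: chamber density, error rates, growth curves.

A hemocytometer counting chamber holds cells over a grid of 1 mm^2 squares
at 0.1 mm depth, so a mean count of C cells per square corresponds to a
suspension density of ``C * dilution * 1e4`` cells/mL.  Detector accuracy
is summarized by the relative count error at each sampled density (ERT)
and its average over all densities (TERT).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .detect import DetectionResult
from .synth import SyntheticScene

__all__ = [
    "CountRecord",
    "ErrorReport",
    "cells_per_ml",
    "error_rate",
    "total_error_rate",
    "growth_curve",
    "match_centers",
    "count_error_report",
]


def cells_per_ml(mean_count_per_region: float,
                 region_area: float = 1.0,
                 chamber_depth: float = 0.1,
                 dilution_factor: float = 1.0) -> float:
    """Convert a mean per-square chamber count to suspension density.

    Parameters are the counting-square area (mm^2), chamber depth (mm) and
    the dilution factor applied before loading the chamber; the counted
    volume per square is ``area * depth`` mm^3 and 1 mL = 1000 mm^3.
    """
    if mean_count_per_region < 0:
        raise ValueError("count must be >= 0")
    if region_area <= 0 or chamber_depth <= 0 or dilution_factor <= 0:
        raise ValueError("area, depth and dilution must be > 0")
    return mean_count_per_region * dilution_factor * 1000.0 / (
        region_area * chamber_depth)


def error_rate(gt_density: float, method_density: float) -> float:
    """Relative count error |method - GT| / GT at one density."""
    if gt_density <= 0:
        raise ValueError("ground-truth density must be > 0")
    return abs(method_density - gt_density) / gt_density


def total_error_rate(report_rows: Sequence[tuple[float, float]]) -> float:
    """Mean relative error over (GT, method) pairs at different densities."""
    rows = list(report_rows)
    if not rows:
        raise ValueError("need at least one (GT, method) pair")
    return float(np.mean([error_rate(gt, m) for gt, m in rows]))


@dataclass(frozen=True)
class CountRecord:
    """Per-sample chamber count at one culture timepoint.

    ``region_counts`` holds the counts of the individual counting squares
    (e.g. squares A1..A5); density is derived, never stored.
    """

    sample_id: str
    timepoint: float  # hours since seeding
    region_counts: tuple[int, ...]
    dilution_factor: float = 1.0
    chamber_depth: float = 0.1  # mm
    region_area: float = 1.0    # mm^2

    def __post_init__(self) -> None:
        if any(c < 0 or int(c) != c for c in self.region_counts):
            raise ValueError("region counts must be non-negative integers")
        if not self.region_counts:
            raise ValueError("need at least one region count")

    @property
    def density(self) -> float:
        """Suspension density in cells/mL."""
        return cells_per_ml(float(np.mean(self.region_counts)),
                            self.region_area, self.chamber_depth,
                            self.dilution_factor)


@dataclass(frozen=True)
class ErrorReport:
    """Per-timepoint relative errors and their mean (TERT)."""

    per_timepoint: pd.DataFrame  # columns: timepoint, gt_density, method_density, ert

    @property
    def tert(self) -> float:
        return float(self.per_timepoint["ert"].mean())

    @property
    def n_timepoints(self) -> int:
        return len(self.per_timepoint)


def count_error_report(gt_densities: Sequence[float],
                       method_densities: Sequence[float],
                       timepoints: Sequence[float] | None = None) -> ErrorReport:
    """Build an :class:`ErrorReport` from paired density series."""
    gt = np.asarray(gt_densities, float)
    meth = np.asarray(method_densities, float)
    if gt.shape != meth.shape or gt.size == 0:
        raise ValueError("density series must be non-empty and equal length")
    t = (np.asarray(timepoints, float) if timepoints is not None
         else np.arange(gt.size, dtype=float))
    df = pd.DataFrame({
        "timepoint": t,
        "gt_density": gt,
        "method_density": meth,
        "ert": [error_rate(g, m) for g, m in zip(gt, meth)],
    })
    return ErrorReport(per_timepoint=df)


def growth_curve(records: Sequence[CountRecord]) -> pd.DataFrame:
    """Density-vs-time series, averaging same-timepoint samples.

    Returns a DataFrame with columns ``timepoint`` (sorted ascending) and
    ``density`` (mean cells/mL over the samples at that timepoint).
    """
    if len({r.timepoint for r in records}) < 2:
        raise ValueError("need at least 2 distinct timepoints")
    keys = [(r.sample_id, r.timepoint) for r in records]
    if len(set(keys)) != len(keys):
        dupes = {k for k in keys if keys.count(k) > 1}
        raise ValueError(f"duplicate (sample_id, timepoint) records: {dupes}")
    df = pd.DataFrame({"timepoint": [r.timepoint for r in records],
                       "density": [r.density for r in records]})
    return (df.groupby("timepoint", as_index=False)["density"].mean()
              .sort_values("timepoint", ignore_index=True))


def match_centers(detected: DetectionResult | np.ndarray,
                  truth: SyntheticScene | np.ndarray,
                  tolerance: float = 3.0) -> tuple[int, int, int]:
    """Greedy nearest-first one-to-one matching of detections to truth.

    Candidate pairs within ``tolerance`` pixels are matched in order of
    increasing distance (ties: lower detection index, then lower truth
    index).  Returns ``(true_positives, false_positives, false_negatives)``
    with TP + FN = number planted and TP + FP = number detected.
    """
    if tolerance <= 0:
        raise ValueError("tolerance must be > 0")
    det = (detected.centers if isinstance(detected, DetectionResult)
           else np.asarray(detected, float).reshape(-1, 2))
    tru = (truth.true_centers if isinstance(truth, SyntheticScene)
           else np.asarray(truth, float).reshape(-1, 2))
    if len(det) == 0 or len(tru) == 0:
        return 0, len(det), len(tru)
    diff = det[:, None, :].astype(float) - tru[None, :, :].astype(float)
    dist = np.hypot(diff[..., 0], diff[..., 1])
    pairs = [(dist[i, j], i, j)
             for i in range(len(det)) for j in range(len(tru))
             if dist[i, j] <= tolerance]
    pairs.sort()
    used_det: set[int] = set()
    used_tru: set[int] = set()
    tp = 0
    for _, i, j in pairs:
        if i in used_det or j in used_tru:
            continue
        used_det.add(i)
        used_tru.add(j)
        tp += 1
    return tp, len(det) - tp, len(tru) - tp
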