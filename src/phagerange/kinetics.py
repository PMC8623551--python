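"""Per-well growth-curve statistics.

Detection time (first reading at or above the OD600 threshold), endpoint
summaries (maximum and time-averaged OD), a rolling least-squares growth
rate, the growth-trend gate used for replicate QC, and optional blank
correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .plate_io import WellSeries


@dataclass(frozen=True)
class CurveSummary:
    """Summary statistics for one well's curve over the analysis window."""

    detection_time: float | None
    od_max: float
    od_mean: float
    trend: bool
    rolling_slopes: np.ndarray


def detection_time(series: WellSeries, threshold: float) -> float | None:
    """Time (h) of the first reading at or above ``threshold``.

    No interpolation: detection is resolved to the reading grid, so its
    granularity is one reading interval.  Returns None when the curve never
    reaches the threshold.
    """
    if len(series) == 0:
        raise ValueError(f"well {series.well}: empty series")
    idx = np.flatnonzero(series.readings >= threshold)
    if idx.size == 0:
        return None
    return float(series.times[idx[0]])


def endpoint_stats(series: WellSeries) -> tuple[float, float]:
    """(od_max, od_mean) over all readings in the window."""
    if len(series) == 0:
        raise ValueError(f"well {series.well}: empty series")
    return float(series.readings.max()), float(series.readings.mean())


def rolling_slope(series: WellSeries, window: int) -> np.ndarray:
    """Least-squares slope (OD/h) of the trailing ``window`` readings.

    Index i holds the slope of readings i-window+1 .. i regressed on their
    times; indices before window-1 are NaN.
    """
    if window < 2:
        raise ValueError("window must be >= 2")
    n = len(series)
    if n < window:
        raise ValueError(f"well {series.well}: {n} readings < window {window}")
    t, y = series.times, series.readings
    out = np.full(n, np.nan)
    for i in range(window - 1, n):
        tw = t[i - window + 1 : i + 1]
        yw = y[i - window + 1 : i + 1]
        tc = tw - tw.mean()
        out[i] = float(np.dot(tc, yw - yw.mean()) / np.dot(tc, tc))
    return out


def growth_trend(series: WellSeries, min_growth_rate: float, window: int) -> bool:
    """True iff any defined rolling slope reaches ``min_growth_rate`` (OD/h)."""
    slopes = rolling_slope(series, window)
    defined = slopes[~np.isnan(slopes)]
    return bool(defined.size and defined.max() >= min_growth_rate)


def blank_correct(series: WellSeries, blanks: Iterable[WellSeries]) -> WellSeries:
    """Subtract the per-timepoint mean of blank wells; clamp at 0 OD."""
    blanks = list(blanks)
    if not blanks:
        return series
    for b in blanks:
        if len(b) != len(series) or not np.allclose(b.times, series.times):
            raise ValueError(
                f"blank {b.well} not time-aligned with {series.well}"
            )
    blank_mean = np.mean([b.readings for b in blanks], axis=0)
    corrected = np.clip(series.readings - blank_mean, 0.0, None)
    return WellSeries(series.well, series.times, corrected)


def summarize_curve(
    series: WellSeries,
    threshold: float,
    min_growth_rate: float,
    window: int,
) -> CurveSummary:
    """All per-well statistics in one pass."""
    od_max, od_mean = endpoint_stats(series)
    slopes = rolling_slope(series, window)
    defined = slopes[~np.isnan(slopes)]
    return CurveSummary(
        detection_time=detection_time(series, threshold),
        od_max=od_max,
        od_mean=od_mean,
        trend=bool(defined.size and defined.max() >= min_growth_rate),
        rolling_slopes=slopes,
    )


def mean_series(replicates: Sequence[WellSeries]) -> WellSeries:
    """Pointwise mean curve of time-aligned replicate wells.

    Used by the alternative classify-the-averaged-curve mode; the averaged
    curve keeps the first replicate's well coordinate.
    """
    if not replicates:
        raise ValueError("no replicates to average")
    first = replicates[0]
    for s in replicates[1:]:
        if not np.allclose(s.times, first.times):
            raise ValueError("replicates not time-aligned")
    mean = np.mean([s.readings for s in replicates], axis=0)
    return WellSeries(first.well, first.times, mean)
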