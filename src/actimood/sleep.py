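"""Sleep window detection and summary sleep measures.

A simple threshold detector finds the main nightly sleep period in each
noon-to-noon day: the longest contiguous block of rolling-median activity
below a participant-specific threshold ``theta`` (a fraction, default 10%, of
the participant's typical daytime activity) lasting at least ``min_block_h``
hours. Epochs inside the window are scored asleep when their raw magnitude is
below ``theta``.

From the per-night windows: *mean sleep duration* is the mean of hours scored
asleep within the window, *mean sleep efficiency* the mean of slept/window
ratios, and duration is categorised as short (< 7 h), regular (7-9 h,
endpoints inclusive) or long (> 9 h).

This detector deliberately does not score naps: one window per day, matching
an objective-duration definition that excludes daytime napping.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional

import numpy as np
import pandas as pd

from .cohort import EpochSeries
from .config import SleepDetectorParams

__all__ = [
    "SleepWindow",
    "SleepMetrics",
    "activity_threshold",
    "detect_sleep_window",
    "detect_all_nights",
    "summarise_sleep",
    "categorize_sleep_duration",
]

SHORT_MAX_H = 7.0  # short: strictly less
LONG_MIN_H = 9.0  # long: strictly more


@dataclass
class SleepWindow:
    day: int
    onset: pd.Timestamp
    offset: pd.Timestamp
    window_hours: float
    slept_hours: float

    def __post_init__(self) -> None:
        if self.offset <= self.onset:
            raise ValueError("offset must be after onset")
        if not (0.0 <= self.slept_hours <= self.window_hours + 1e-9):
            raise ValueError("slept_hours must be within [0, window_hours]")

    @property
    def efficiency(self) -> float:
        return self.slept_hours / self.window_hours


@dataclass
class SleepMetrics:
    mean_sleep_duration: float
    mean_sleep_efficiency: float
    duration_category: Optional[str]
    n_valid_nights: int


def activity_threshold(
    series: EpochSeries, threshold_frac: float = 0.10, daytime_quantile: float = 0.75
) -> float:
    """theta: fraction of the participant's typical daytime magnitude.

    The daytime reference is an upper quantile (default 75th percentile) of
    all worn epochs: sleep plus rest bouts can occupy more than half the day,
    so the plain median can collapse to the sleep level, while the upper
    quartile stays in the daytime activity range.
    """
    worn = series.values[series.wear]
    if worn.size == 0:
        raise ValueError("no worn epochs")
    return threshold_frac * float(np.quantile(worn, daytime_quantile))


def _rolling_median(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    if width % 2 == 0:
        width += 1  # keep the window centred
    return (
        pd.Series(x).rolling(width, center=True, min_periods=1).median().to_numpy()
    )


def _longest_true_run(mask: np.ndarray) -> tuple:
    """(start, stop) of the longest run of True; earliest wins ties."""
    best = (0, 0)
    i = 0
    n = mask.size
    while i < n:
        if mask[i]:
            j = i
            while j < n and mask[j]:
                j += 1
            if j - i > best[1] - best[0]:
                best = (i, j)
            i = j
        else:
            i += 1
    return best


def detect_sleep_window(
    series: EpochSeries,
    day: int,
    params: SleepDetectorParams | None = None,
    theta: float | None = None,
) -> Optional[SleepWindow]:
    """Detect the main sleep period of one noon-to-noon day.

    Returns None (invalid night) when the day has insufficient wear or no
    low-activity block of at least ``min_block_h`` hours exists.
    """
    params = params or SleepDetectorParams()
    ne_day = series.epochs_per_day
    if not (0 <= day < series.n_days):
        raise ValueError(f"day {day} outside series ({series.n_days} days)")
    sl = slice(day * ne_day, (day + 1) * ne_day)
    vals, wear = series.values[sl], series.wear[sl]
    epoch_h = series.epoch_s / 3600.0
    if wear.sum() * epoch_h < params.min_wear_h:
        return None
    if theta is None:
        theta = activity_threshold(series, params.threshold_frac, params.daytime_quantile)

    width = max(int(round(params.smoothing_min * 60 / series.epoch_s)), 1)
    smoothed = _rolling_median(np.where(wear, vals, np.nan), width)
    below = np.nan_to_num(smoothed, nan=np.inf) < theta
    start, stop = _longest_true_run(below)
    if (stop - start) * epoch_h < params.min_block_h:
        return None

    in_window = vals[start:stop]
    asleep = in_window < theta
    onset = series.start + pd.Timedelta(seconds=(day * ne_day + start) * series.epoch_s)
    offset = series.start + pd.Timedelta(seconds=(day * ne_day + stop) * series.epoch_s)
    return SleepWindow(
        day=day,
        onset=onset,
        offset=offset,
        window_hours=(stop - start) * epoch_h,
        slept_hours=float(asleep.sum()) * epoch_h,
    )


def detect_all_nights(
    series: EpochSeries, params: SleepDetectorParams | None = None
) -> List[SleepWindow]:
    params = params or SleepDetectorParams()
    theta = activity_threshold(series, params.threshold_frac, params.daytime_quantile)
    windows = []
    for d in range(series.n_days):
        w = detect_sleep_window(series, d, params, theta=theta)
        if w is not None:
            windows.append(w)
    return windows


def categorize_sleep_duration(hours: float) -> str:
    """short (< 7 h) / regular (7-9 h inclusive) / long (> 9 h)."""
    if pd.isna(hours):
        raise ValueError("sleep duration is missing")
    if hours < 0:
        raise ValueError(f"negative sleep duration: {hours}")
    if hours < SHORT_MAX_H:
        return "short"
    if hours > LONG_MIN_H:
        return "long"
    return "regular"


def summarise_sleep(windows: List[SleepWindow]) -> SleepMetrics:
    """Mean duration/efficiency over valid nights; NaNs when none qualify."""
    if not windows:
        return SleepMetrics(float("nan"), float("nan"), None, 0)
    duration = float(np.mean([w.slept_hours for w in windows]))
    efficiency = float(np.mean([w.efficiency for w in windows]))
    return SleepMetrics(
        mean_sleep_duration=duration,
        mean_sleep_efficiency=efficiency,
        duration_category=categorize_sleep_duration(duration),
        n_valid_nights=len(windows),
    )
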