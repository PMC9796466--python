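"""Nonparametric rest-activity rhythm metrics.

Computes the classic nonparametric circadian variables from an epoch-level
acceleration series:

* **AA** — average acceleration, the mean worn-epoch magnitude over the whole
  record (milli-g).
* **M10 / L5** — mean magnitude of the most active contiguous 10-hour and
  least active contiguous 5-hour window of a day, windows sliding at epoch
  resolution within a noon-to-noon day.
* **RA** — relative amplitude, ``(M10 - L5) / (M10 + L5)`` per day, averaged
  across days (optionally computed from across-day average M10/L5 instead).
* **IS** — interdaily stability on hourly means ``x_i`` with clock-hour means
  ``xbar_h``:  ``IS = (N * sum_h (xbar_h - xbar)^2) / (24 * sum_i (x_i - xbar)^2)``,
  in [0, 1]; 1 when every day repeats the same 24-h profile.
* **IV** — intradaily variability,
  ``IV = (N * sum_{i>=2} (x_i - x_{i-1})^2) / ((N - 1) * sum_i (x_i - xbar)^2)``,
  >= 0; about 2 for white noise, higher for fragmented rhythms.

Undefined values (constant signal, no valid days) propagate as NaN, never as
zeros. Days with under ``min_day_hours`` (default 20) of complete hourly data
are dropped from IS/IV/RA with a logged count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional

import numpy as np

from .cohort import EpochSeries

__all__ = [
    "HourlySeries",
    "RhythmMetrics",
    "bin_hourly",
    "average_acceleration",
    "interdaily_stability",
    "intradaily_variability",
    "relative_amplitude",
    "compute_rhythm_metrics",
]

log = logging.getLogger(__name__)

HOURS_PER_DAY = 24


@dataclass
class HourlySeries:
    """Hourly mean magnitudes aligned to clock hours.

    ``values[i]`` is the mean worn-epoch magnitude of hour ``i`` after the
    series start (NaN where completeness is below threshold);
    ``start_clock_hour`` anchors index 0 to the clock.
    """

    values: np.ndarray
    completeness: np.ndarray
    start_clock_hour: int

    @property
    def n_hours(self) -> int:
        return self.values.size

    def clock_hours(self) -> np.ndarray:
        return (self.start_clock_hour + np.arange(self.n_hours)) % HOURS_PER_DAY


def bin_hourly(
    series: EpochSeries,
    completeness_min: float = 0.5,
    strict: bool = False,
) -> HourlySeries:
    """Average epochs into clock-aligned hourly bins.

    Hours whose worn fraction falls below ``completeness_min`` are NaN; with
    ``strict=True`` such hours raise instead.
    """
    if series.n_epochs == 0:
        raise ValueError("empty series")
    per_hour = 3600 // series.epoch_s
    n_hours = series.n_epochs // per_hour
    if n_hours == 0:
        raise ValueError("series shorter than one hour")
    vals = series.values[: n_hours * per_hour].reshape(n_hours, per_hour)
    wear = series.wear[: n_hours * per_hour].reshape(n_hours, per_hour)

    worn_counts = wear.sum(axis=1)
    completeness = worn_counts / per_hour
    with np.errstate(invalid="ignore"):
        sums = np.where(wear, vals, 0.0).sum(axis=1)
        means = np.where(worn_counts > 0, sums / np.maximum(worn_counts, 1), np.nan)
    means = np.where(completeness >= completeness_min, means, np.nan)
    if strict and np.isnan(means).any():
        bad = np.flatnonzero(np.isnan(means)).tolist()
        raise ValueError(f"hours below completeness threshold: {bad}")
    return HourlySeries(values=means, completeness=completeness,
                        start_clock_hour=int(series.start.hour))


def average_acceleration(series: EpochSeries) -> float:
    """Mean worn-epoch magnitude over the full record (milli-g)."""
    worn = series.values[series.wear]
    if worn.size == 0:
        raise ValueError("no worn epochs")
    return float(worn.mean())


def _complete_day_values(hourly: HourlySeries, min_day_hours: float) -> np.ndarray:
    """Stack retained days as a (d, 24) array with NaN gaps, dropping short days."""
    n_days = hourly.n_hours // HOURS_PER_DAY
    if n_days == 0:
        raise ValueError("need at least 24 hourly values")
    x = hourly.values[: n_days * HOURS_PER_DAY].reshape(n_days, HOURS_PER_DAY)
    valid = (~np.isnan(x)).sum(axis=1) >= min_day_hours
    dropped = int(n_days - valid.sum())
    if dropped:
        log.info("dropping %d day(s) below %.0f complete hours", dropped, min_day_hours)
    return x[valid]


def interdaily_stability(hourly: HourlySeries, min_day_hours: float = 20.0) -> float:
    """Coupling of the hourly profile to a 24-hour pattern, in [0, 1].

    NaN when fewer than 2 retained days or when the signal is constant
    (zero total variance makes the ratio undefined).
    """
    days = _complete_day_values(hourly, min_day_hours)
    if days.shape[0] < 2:
        return float("nan")
    flat = days.ravel()
    mask = ~np.isnan(flat)
    xbar = flat[mask].mean()
    n = int(mask.sum())
    denom = np.nansum((flat - xbar) ** 2)
    if denom <= 0:
        return float("nan")
    hour_means = np.nanmean(days, axis=0)
    num = n * np.nansum((hour_means - xbar) ** 2)
    return float(num / (HOURS_PER_DAY * denom))


def intradaily_variability(hourly: HourlySeries, min_day_hours: float = 20.0) -> float:
    """Normalised squared successive difference of hourly values, >= 0.

    Differences are taken between consecutive retained hourly values; NaN on
    constant signals.
    """
    days = _complete_day_values(hourly, min_day_hours)
    flat = days.ravel()
    x = flat[~np.isnan(flat)]
    n = x.size
    if n < HOURS_PER_DAY:
        raise ValueError("need at least 24 hourly values")
    xbar = x.mean()
    denom = ((x - xbar) ** 2).sum()
    if denom <= 0:
        return float("nan")
    num = n * (np.diff(x) ** 2).sum()
    return float(num / ((n - 1) * denom))


def _sliding_means(day_values: np.ndarray, width: int) -> np.ndarray:
    """Means of all contiguous windows of ``width`` epochs (no wrap-around)."""
    c = np.concatenate([[0.0], np.cumsum(day_values)])
    return (c[width:] - c[:-width]) / width


def relative_amplitude(
    series: EpochSeries,
    per_day: bool = True,
    min_day_wear_h: float = 20.0,
) -> tuple:
    """(M10, L5, RA) from noon-to-noon days.

    Per day, M10 (L5) is the max (min) mean over contiguous 10-h (5-h)
    windows sliding at epoch resolution within the day, and
    ``RA = (M10 - L5) / (M10 + L5)``. With ``per_day=True`` (default) daily
    RA values are averaged; otherwise RA is formed from the across-day mean
    M10 and L5. Days with insufficient wear, or with ``M10 + L5 == 0``, are
    dropped with a log entry. Returns NaNs when no day qualifies.
    """
    ne_day = series.epochs_per_day
    n_days = series.n_days
    if n_days < 1:
        raise ValueError("need at least one complete day")
    w10 = int(round(10 * 3600 / series.epoch_s))
    w5 = int(round(5 * 3600 / series.epoch_s))

    m10s, l5s, ras = [], [], []
    for d in range(n_days):
        sl = slice(d * ne_day, (d + 1) * ne_day)
        vals, wear = series.values[sl], series.wear[sl]
        if wear.sum() * series.epoch_s / 3600.0 < min_day_wear_h:
            log.info("RA: dropping day %d (insufficient wear)", d)
            continue
        day = np.where(wear, vals, np.nan)
        # fill short non-wear gaps with the day's worn mean so windows stay defined
        if np.isnan(day).any():
            day = np.where(np.isnan(day), np.nanmean(day), day)
        m10 = float(_sliding_means(day, w10).max())
        l5 = float(_sliding_means(day, w5).min())
        if m10 + l5 <= 0:
            log.info("RA: dropping day %d (M10 + L5 = 0)", d)
            continue
        m10s.append(m10)
        l5s.append(l5)
        ras.append((m10 - l5) / (m10 + l5))
    if not ras:
        return float("nan"), float("nan"), float("nan")
    m10_mean, l5_mean = float(np.mean(m10s)), float(np.mean(l5s))
    if per_day:
        ra = float(np.mean(ras))
    else:
        ra = (m10_mean - l5_mean) / (m10_mean + l5_mean)
    return m10_mean, l5_mean, ra


@dataclass
class RhythmMetrics:
    aa: float
    m10: float
    l5: float
    ra: float
    is_: float
    iv: float
    n_valid_days: int


def compute_rhythm_metrics(
    series: EpochSeries,
    per_day_ra: bool = True,
    hourly_completeness_min: float = 0.5,
    min_day_hours: float = 20.0,
) -> RhythmMetrics:
    """All rhythm metrics for one participant's series."""
    hourly = bin_hourly(series, completeness_min=hourly_completeness_min)
    n_days = series.n_days
    days = _complete_day_values(hourly, min_day_hours) if n_days >= 1 else np.empty((0, 24))
    m10, l5, ra = relative_amplitude(series, per_day=per_day_ra, min_day_wear_h=min_day_hours)
    return RhythmMetrics(
        aa=average_acceleration(series),
        m10=m10,
        l5=l5,
        ra=ra,
        is_=interdaily_stability(hourly, min_day_hours) if n_days >= 2 else float("nan"),
        iv=intradaily_variability(hourly, min_day_hours),
        n_valid_days=int(days.shape[0]),
    )
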