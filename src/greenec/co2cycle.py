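"""Station CO2 record diagnostics: detrended seasonal cycles and the
summertime drawdown-slope change statistic.

The drawdown slope is the annual minimum of the month-to-month first
difference of the concentration record — the steepest summertime decline,
in ppm month⁻¹, driven by photosynthetic CO2 fixation. Because first
differencing removes any constant and converts a linear trend into a
constant monthly increment, the change in drawdown slope between the start
and end of a record needs no detrending. Changes are computed from 5-year
averages at the two ends of a (nominally 30-year) window after lightly
smoothing the yearly series with a 2-year moving window.
"""
from __future__ import annotations

import warnings
from collections import Counter
from dataclasses import dataclass

import numpy as np

__all__ = [
    "StationRecord",
    "DrawdownResult",
    "detrended_seasonal_cycle",
    "seasonal_amplitude",
    "drawdown_change",
]


@dataclass
class StationRecord:
    """Monthly CO2 concentrations at one station; NaN flags missing months."""

    station: str
    year: np.ndarray
    month: np.ndarray
    ppm: np.ndarray
    lat: float | None = None
    lon: float | None = None

    def __post_init__(self) -> None:
        self.year = np.asarray(self.year, dtype=int)
        self.month = np.asarray(self.month, dtype=int)
        self.ppm = np.asarray(self.ppm, dtype=float)
        if not (self.year.size == self.month.size == self.ppm.size):
            raise ValueError("year, month and ppm must have equal length")
        if np.any((self.month < 1) | (self.month > 12)):
            raise ValueError("months must lie in 1..12")
        t = self.year * 12 + (self.month - 1)
        if np.any(np.diff(t) <= 0):
            raise ValueError("timestamps must be strictly increasing")

    def complete(self) -> "StationRecord":
        """Re-index onto a gapless monthly axis, NaN-filling absent months."""
        t = self.year * 12 + (self.month - 1)
        full = np.arange(t[0], t[-1] + 1)
        ppm = np.full(full.size, np.nan)
        ppm[t - t[0]] = self.ppm
        return StationRecord(
            self.station, full // 12, full % 12 + 1, ppm, self.lat, self.lon
        )

    def window(self, start_year: int, end_year: int) -> "StationRecord":
        sel = (self.year >= start_year) & (self.year <= end_year)
        if not np.any(sel):
            raise ValueError(f"window {start_year}-{end_year} outside record")
        return StationRecord(
            self.station, self.year[sel], self.month[sel], self.ppm[sel], self.lat, self.lon
        )


def _running_annual_mean(ppm: np.ndarray) -> np.ndarray:
    """Centered 12-month running mean (13-point window, half-weight ends)."""
    kernel = np.ones(13)
    kernel[0] = kernel[-1] = 0.5
    kernel /= 12.0
    out = np.full(ppm.size, np.nan)
    if ppm.size >= 13:
        conv = np.convolve(ppm, kernel, mode="valid")
        out[6 : 6 + conv.size] = conv
    return out


def detrended_seasonal_cycle(
    rec: StationRecord, epoch: tuple[int, int], max_missing_frac: float = 0.2
) -> np.ndarray:
    """Mean detrended seasonal cycle over an epoch (12 monthly anomalies).

    A centered 12-month running mean (the local annual baseline) is
    subtracted from the gapless record, and the residual anomalies are
    averaged by calendar month over the epoch years. Anomalies sum to ≈ 0.
    """
    y0, y1 = epoch
    if y1 - y0 + 1 < 4:
        raise ValueError("epoch must cover at least 4 years")
    full = rec.complete()
    anom = full.ppm - _running_annual_mean(full.ppm)
    in_epoch = (full.year >= y0) & (full.year <= y1)
    if not np.any(in_epoch):
        raise ValueError(f"epoch {y0}-{y1} outside record")
    missing = np.mean(~np.isfinite(full.ppm[in_epoch]))
    if missing > max_missing_frac:
        raise ValueError(
            f"{missing:.0%} of months missing in epoch {y0}-{y1} "
            f"(limit {max_missing_frac:.0%})"
        )
    out = np.full(12, np.nan)
    for m in range(1, 13):
        sel = in_epoch & (full.month == m) & np.isfinite(anom)
        if np.any(sel):
            out[m - 1] = anom[sel].mean()
    return out


def seasonal_amplitude(rec: StationRecord, epoch: tuple[int, int]) -> float:
    """Peak-to-trough amplitude of the detrended seasonal cycle (diagnostic).

    Provided for comparison only; the drawdown slope is the preferred GPP
    proxy since the amplitude also responds to wintertime respiration.
    """
    cyc = detrended_seasonal_cycle(rec, epoch)
    return float(np.nanmax(cyc) - np.nanmin(cyc))


@dataclass
class DrawdownResult:
    """Yearly drawdown-slope series and its change over the window."""

    years: np.ndarray
    slopes: np.ndarray  # ppm/month, annual min of the monthly first difference
    smoothed: np.ndarray
    change: float  # ppm/month over the window (end minus start 5-yr means)
    change_sd: float
    drawdown_months: np.ndarray  # calendar month of each year's minimum


def _interpolate_short_gaps(ppm: np.ndarray, max_gap: int = 2) -> np.ndarray:
    """Linearly fill interior NaN runs of length <= max_gap."""
    out = ppm.copy()
    isnan = ~np.isfinite(out)
    i = 0
    n = out.size
    while i < n:
        if isnan[i]:
            j = i
            while j < n and isnan[j]:
                j += 1
            if 0 < i and j < n and (j - i) <= max_gap:
                out[i:j] = np.interp(np.arange(i, j), [i - 1, j], [out[i - 1], out[j]])
            i = j
        else:
            i += 1
    return out


def drawdown_change(
    rec: StationRecord,
    window: tuple[int, int] | None = None,
    min_years: int = 30,
    max_missing_frac: float = 0.10,
    end_mean_years: int = 5,
) -> DrawdownResult:
    """Change in the summertime CO2 drawdown slope over a multi-decade window.

    Per year the slope is the minimum forward first difference of the
    monthly concentrations (ppm month⁻¹); gaps of ≤ 2 months are linearly
    interpolated, longer gaps invalidate the year. The yearly series is
    smoothed with a 2-year moving window and the change taken as the
    difference of the 5-year means at the end and start of the record, its
    sd the quadrature combination of the two 5-year window sds.
    """
    if window is not None:
        rec = rec.window(*window)
    full = rec.complete()
    n_years = full.year[-1] - full.year[0] + 1
    if n_years < min_years:
        raise ValueError(f"window spans {n_years} years; need >= {min_years}")
    missing = np.mean(~np.isfinite(full.ppm))
    if missing > max_missing_frac:
        raise ValueError(
            f"{missing:.0%} of months missing (limit {max_missing_frac:.0%})"
        )
    ppm = _interpolate_short_gaps(full.ppm)
    diffs = np.diff(ppm)  # forward difference, assigned to the left month
    dyear = full.year[:-1]
    dmonth = full.month[:-1]
    years = np.arange(full.year[0], full.year[-1] + 1)
    slopes = np.full(years.size, np.nan)
    months = np.full(years.size, -1)
    for i, yr in enumerate(years):
        sel = dyear == yr
        d = diffs[sel]
        if d.size < 12 or not np.all(np.isfinite(d)):
            continue  # long gap invalidates the year
        k = int(np.argmin(d))
        slopes[i] = d[k]
        months[i] = dmonth[sel][k]
    valid = np.isfinite(slopes)
    if valid.sum() < 2 * end_mean_years:
        raise ValueError("too few valid years for start/end averaging")
    mseason = Counter(months[valid]).most_common(1)[0]
    if mseason[1] < 0.5 * valid.sum():
        warnings.warn(
            "drawdown month is not concentrated in a single season; "
            "proceeding on the global minimum",
            stacklevel=2,
        )
    # 2-year moving window: mean of the year and its successor
    smoothed = slopes.copy()
    for i in range(years.size - 1):
        pair = slopes[i : i + 2]
        if np.any(np.isfinite(pair)):
            smoothed[i] = np.nanmean(pair)
    head = smoothed[:end_mean_years]
    tail = smoothed[-end_mean_years:]
    change = float(np.nanmean(tail) - np.nanmean(head))
    change_sd = float(np.hypot(np.nanstd(tail, ddof=1), np.nanstd(head, ddof=1)))
    return DrawdownResult(years, slopes, smoothed, change, change_sd, months)
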