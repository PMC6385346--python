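"""Core data containers: annual scalar series and gridded monthly fields.

All missing data is represented as NaN; masks are therefore implicit and
always aligned with the values they flag.
"""
from __future__ import annotations

import calendar as _cal
from dataclasses import dataclass, field

import numpy as np

__all__ = ["AnnualSeries", "MonthlyField", "days_in_months"]

_DAYS_NOLEAP = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)


def days_in_months(year: int, calendar: str = "gregorian") -> np.ndarray:
    """Days per month for one year under the dataset's calendar.

    ``gregorian`` is leap-aware; ``noleap``/``365_day`` is the fixed model
    calendar; ``360_day`` has twelve 30-day months.
    """
    cal = calendar.lower()
    if cal in ("gregorian", "standard", "proleptic_gregorian"):
        days = _DAYS_NOLEAP.copy()
        if _cal.isleap(int(year)):
            days[1] = 29.0
        return days
    if cal in ("noleap", "365_day"):
        return _DAYS_NOLEAP.copy()
    if cal == "360_day":
        return np.full(12, 30.0)
    raise ValueError(f"unknown calendar {calendar!r}")


@dataclass
class AnnualSeries:
    """A contiguous year-indexed scalar series with units.

    Holds LAI_max, GDD0, annual-mean CO2 or the PCA driver ω. Missing years
    are NaN entries; the year axis itself is gapless and strictly increasing.
    """

    years: np.ndarray
    values: np.ndarray
    label: str = ""
    units: str = ""

    def __post_init__(self) -> None:
        self.years = np.asarray(self.years, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if self.years.ndim != 1 or self.values.ndim != 1:
            raise ValueError("years and values must be 1-D")
        if self.years.size != self.values.size:
            raise ValueError("years and values must have equal length")
        if self.years.size == 0:
            raise ValueError("empty series")
        d = np.diff(self.years)
        if np.any(d != 1):
            raise ValueError("years must be contiguous and strictly increasing")

    def __len__(self) -> int:
        return self.years.size

    def align(self, other: "AnnualSeries") -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Common years and the corresponding value arrays of self and other."""
        common, ia, ib = np.intersect1d(self.years, other.years, return_indices=True)
        if common.size == 0:
            raise ValueError("series have no overlapping years")
        return common, self.values[ia], other.values[ib]

    def window(self, start: int, end: int) -> "AnnualSeries":
        """Sub-series on the closed year range [start, end]."""
        sel = (self.years >= start) & (self.years <= end)
        if not np.any(sel):
            raise ValueError(f"window {start}-{end} does not overlap series")
        return AnnualSeries(self.years[sel], self.values[sel], self.label, self.units)


@dataclass
class MonthlyField:
    """Gridded monthly values on a regular lat/lon grid.

    ``values`` has shape (n_years, 12, n_lat, n_lon); NaN marks missing
    cells or months.
    """

    values: np.ndarray
    years: np.ndarray
    lats: np.ndarray
    lons: np.ndarray
    units: str = ""
    calendar: str = "gregorian"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        self.lats = np.asarray(self.lats, dtype=float)
        self.lons = np.asarray(self.lons, dtype=float)
        if self.values.ndim != 4 or self.values.shape[1] != 12:
            raise ValueError("values must have shape (n_years, 12, n_lat, n_lon)")
        if self.values.shape[0] != self.years.size:
            raise ValueError("year axis mismatch")
        if self.values.shape[2] != self.lats.size or self.values.shape[3] != self.lons.size:
            raise ValueError("grid axis mismatch")
        if np.any(np.abs(self.lats) > 90.0):
            raise ValueError("latitudes must lie within [-90, 90]")
        if np.any(np.diff(self.years) != 1):
            raise ValueError("years must be contiguous")
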