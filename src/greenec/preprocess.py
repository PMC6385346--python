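"""Reduction of gridded monthly fields to annual NHL scalar series, and
construction of the proxy driver ω.

The analysis needs four annual series for the 60°N-90°N band: the annual
maximum leaf area index (LAI_max), growing degree days above 0 °C (GDD0),
the annual-mean CO2 concentration, and their combination ω — the first
principal component of the two standardized drivers (CO2, GDD0). PCA is
used because the two drivers are strongly collinear over the historical
period: rather than attempting a factor separation, the shared signal is
captured in a single axis with maximal variance.
"""
from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from .containers import AnnualSeries, MonthlyField, days_in_months

__all__ = [
    "merge_bimonthly_to_monthly",
    "annual_lai_max",
    "area_weighted_nhl_mean",
    "summer_mean_field",
    "compute_gdd0",
    "standardize",
    "first_principal_component",
    "DriverPCA",
]


def merge_bimonthly_to_monthly(
    composites: Iterable[tuple[_dt.date, np.ndarray]],
    lats: np.ndarray,
    lons: np.ndarray,
    units: str = "m2 m-2",
) -> MonthlyField:
    """Average 15-day (bi-monthly) composites into calendar months.

    Each month may carry one or two composites; their arithmetic mean is
    the monthly value, a single composite passes through, and a month with
    no composite is flagged missing (NaN), never zero.
    """
    lats = np.asarray(lats, dtype=float)
    lons = np.asarray(lons, dtype=float)
    groups: dict[tuple[int, int], list[np.ndarray]] = {}
    for date, arr in composites:
        key = (date.year, date.month)
        groups.setdefault(key, []).append(np.asarray(arr, dtype=float))
    if not groups:
        raise ValueError("no composites supplied")
    for key, items in groups.items():
        if len(items) > 2:
            raise ValueError(f"month {key} has {len(items)} composites (max 2)")
    y0 = min(k[0] for k in groups)
    y1 = max(k[0] for k in groups)
    years = np.arange(y0, y1 + 1)
    values = np.full((years.size, 12, lats.size, lons.size), np.nan)
    for (yr, mo), items in groups.items():
        with np.errstate(invalid="ignore"):
            values[yr - y0, mo - 1] = np.mean(np.stack(items), axis=0)
    return MonthlyField(values, years, lats, lons, units=units)


def annual_lai_max(
    years: np.ndarray,
    monthly: np.ndarray,
    min_months: int = 6,
    label: str = "LAI_max",
    units: str = "m2 m-2",
) -> AnnualSeries:
    """Annual maximum of a monthly scalar series.

    ``monthly`` has shape (n_years, 12) with NaN for missing months. A year
    enters the series only if at least ``min_months`` months are present;
    otherwise the year is kept as a missing (NaN) entry.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.ndim != 2 or monthly.shape[1] != 12:
        raise ValueError("monthly must have shape (n_years, 12)")
    n_valid = np.sum(np.isfinite(monthly), axis=1)
    out = np.full(monthly.shape[0], np.nan)
    ok = n_valid >= max(1, min_months)
    if np.any(ok):
        with np.errstate(all="ignore"):
            out[ok] = np.nanmax(monthly[ok], axis=1)
    return AnnualSeries(np.asarray(years, dtype=int), out, label=label, units=units)


def area_weighted_nhl_mean(
    field: MonthlyField, band: tuple[float, float] = (60.0, 90.0)
) -> np.ndarray:
    """Cosine-latitude area-weighted spatial mean over a latitude band.

    Cell membership is by cell-center latitude on the closed band; masked
    (NaN) cells are excluded and the weights renormalized per time step, so
    a uniform field returns its value exactly for any mask. Returns an
    array of shape (n_years, 12); an all-masked time step is NaN.
    """
    lo, hi = band
    if lo >= hi:
        raise ValueError("band must satisfy lo < hi")
    sel = (field.lats >= lo) & (field.lats <= hi)
    if not np.any(sel):
        raise ValueError(f"latitude band [{lo}, {hi}] does not intersect the grid")
    vals = field.values[:, :, sel, :]
    w = np.cos(np.deg2rad(field.lats[sel]))[:, None] * np.ones(field.lons.size)[None, :]
    finite = np.isfinite(vals)
    wsum = np.where(finite, w, 0.0).sum(axis=(2, 3))
    vsum = np.nansum(np.where(finite, vals * w, 0.0), axis=(2, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(wsum > 0, vsum / wsum, np.nan)
    return out


def summer_mean_field(
    field: MonthlyField, months: Sequence[int] = (6, 7, 8)
) -> np.ndarray:
    """Per-pixel summer (default June-August) mean, shape (n_years, n_lat, n_lon)."""
    idx = [m - 1 for m in months]
    with np.errstate(all="ignore"):
        return np.nanmean(field.values[:, idx], axis=1)


def compute_gdd0(
    years: np.ndarray,
    monthly_temp: np.ndarray,
    calendar: str = "gregorian",
    allow_missing: bool = False,
) -> AnnualSeries:
    """Growing degree days above 0 °C from monthly-mean temperatures.

    GDD0 = Σ_m days_m · T_m · 1[T_m > 0], with days per month taken from
    the dataset's calendar. The sum captures both warming and growing
    season prolongation. A missing month is an error unless
    ``allow_missing`` (a completeness policy) is set, in which case the
    month simply does not contribute.
    """
    years = np.asarray(years, dtype=int)
    monthly_temp = np.asarray(monthly_temp, dtype=float)
    if monthly_temp.ndim != 2 or monthly_temp.shape[1] != 12:
        raise ValueError("monthly_temp must have shape (n_years, 12)")
    if not allow_missing and not np.all(np.isfinite(monthly_temp)):
        raise ValueError("GDD0 requires all 12 monthly means (set allow_missing to relax)")
    out = np.empty(years.size)
    for i, yr in enumerate(years):
        days = days_in_months(int(yr), calendar)
        t = monthly_temp[i]
        contrib = np.where(np.isfinite(t) & (t > 0.0), days * t, 0.0)
        out[i] = contrib.sum()
    return AnnualSeries(years, out, label="GDD0", units="degC day")


def standardize(series: AnnualSeries, divisor: str = "n") -> AnnualSeries:
    """Center on the mean and scale to unit variance (population convention).

    The default divisor is n, matching the 1/n covariance normalization of
    the PCA; ``divisor="n-1"`` gives the sample convention.
    """
    v = series.values
    if not np.all(np.isfinite(v)):
        raise ValueError("cannot standardize a series with missing values")
    ddof = 0 if divisor == "n" else 1
    sd = np.std(v, ddof=ddof)
    if sd == 0.0:
        raise ValueError(f"series {series.label!r} is constant (zero variance)")
    return AnnualSeries(
        series.years, (v - v.mean()) / sd, label=series.label, units="1"
    )


@dataclass
class DriverPCA:
    """First-principal-component reduction of two standardized drivers.

    ``eigenvectors`` holds u_k as columns, ordered by descending eigenvalue;
    ``omega`` is the projection of the standardized drivers onto u_1, sign
    oriented so the CO2 loading is positive (ω increases with CO2).
    """

    means: np.ndarray
    sds: np.ndarray
    eigenvectors: np.ndarray
    eigenvalues: np.ndarray
    omega: AnnualSeries
    labels: tuple[str, str] = ("CO2", "GDD0")

    @property
    def explained_fraction(self) -> float:
        return float(self.eigenvalues[0] / self.eigenvalues.sum())


def first_principal_component(co2: AnnualSeries, gdd0: AnnualSeries) -> DriverPCA:
    """ω: the leading PC of standardized annual CO2 and GDD0.

    Both series are standardized (divisor n), the 2x2 covariance matrix
    C = XᵀX / n is eigendecomposed, and ω = X u₁. The sign of u₁ is fixed
    so that the CO2 loading is positive, making "sensitivity to ω" the
    response to increasing CO2 / warmth for every dataset.
    """
    if not np.array_equal(co2.years, gdd0.years):
        raise ValueError("driver series must cover identical year ranges")
    n = len(co2)
    if n < 3:
        raise ValueError("need at least 3 years for the PCA")
    means = np.array([co2.values.mean(), gdd0.values.mean()])
    sds = np.array([np.std(co2.values), np.std(gdd0.values)])
    z1 = standardize(co2).values
    z2 = standardize(gdd0).values
    X = np.column_stack([z1, z2])
    C = X.T @ X / n
    evals, evecs = np.linalg.eigh(C)  # ascending
    order = np.argsort(evals)[::-1]
    evals = evals[order]
    evecs = evecs[:, order]
    if abs(evals[0] - evals[1]) < 1e-12:
        raise ValueError(
            "degenerate PCA: the two driver eigenvalues coincide (isotropic "
            "covariance); the leading axis is undefined"
        )
    u1 = evecs[:, 0]
    # orient so that omega responds positively to the CO2 driver
    if u1[0] < 0 or (u1[0] == 0 and u1[1] < 0):
        evecs = evecs.copy()
        evecs[:, 0] = -evecs[:, 0]
        u1 = evecs[:, 0]
    omega = AnnualSeries(co2.years, X @ u1, label="omega", units="1")
    return DriverPCA(means, sds, evecs, evals, omega, labels=(co2.label or "CO2", gdd0.label or "GDD0"))
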