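"""Readers and writers for the standard input/output formats.

Gridded monthly fields travel as CF-style NetCDF (written in the classic
format through xarray's scipy backend); annual CO2 as two-column CSV;
station records either in the NOAA/ESRL monthly text layout
(whitespace-delimited ``site year month value`` with -999.99 for missing)
or a generic ``year,month,ppm`` CSV; ensemble points as CSV; results as
JSON.
"""
from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import xarray as xr

from .containers import AnnualSeries, MonthlyField
from .co2cycle import StationRecord
from .emergent_constraint import ConstraintResult, EnsemblePoint

__all__ = [
    "read_monthly_field",
    "write_monthly_field",
    "read_annual_co2_csv",
    "write_annual_series_csv",
    "read_noaa_monthly",
    "read_station_csv",
    "write_station_csv",
    "read_ensemble_csv",
    "write_ensemble_csv",
    "write_result_json",
]

_LAT_NAMES = ("lat", "latitude", "y")
_LON_NAMES = ("lon", "longitude", "x")
_TIME_NAMES = ("time", "date")
_MISSING_NOAA = -999.99


def _find_dim(ds: xr.Dataset, candidates, kind: str) -> str:
    for name in ds.dims:
        da = ds.coords.get(name)
        units = str(da.attrs.get("units", "")).lower() if da is not None else ""
        if str(name).lower() in candidates:
            return str(name)
        if kind == "lat" and "degrees_north" in units:
            return str(name)
        if kind == "lon" and "degrees_east" in units:
            return str(name)
    raise ValueError(f"could not identify the {kind} dimension in {list(ds.dims)}")


def read_monthly_field(path, var: str | None = None) -> MonthlyField:
    """Read a CF monthly lat/lon field into a MonthlyField.

    Dimension order and names are auto-detected from coordinate names and
    ``units`` attributes; months absent from the file are NaN-filled.
    """
    ds = xr.open_dataset(path)
    try:
        if var is None:
            cands = [v for v in ds.data_vars if ds[v].ndim == 3]
            if len(cands) != 1:
                raise ValueError(f"specify var; found {list(ds.data_vars)}")
            var = cands[0]
        lat = _find_dim(ds, _LAT_NAMES, "lat")
        lon = _find_dim(ds, _LON_NAMES, "lon")
        time = _find_dim(ds, _TIME_NAMES, "time")
        da = ds[var].transpose(time, lat, lon)
        idx = ds.indexes[time]
        yrs = np.asarray(idx.year)
        mos = np.asarray(idx.month)
        y0, y1 = int(yrs.min()), int(yrs.max())
        years = np.arange(y0, y1 + 1)
        values = np.full((years.size, 12, da.sizes[lat], da.sizes[lon]), np.nan)
        values[yrs - y0, mos - 1] = np.asarray(da.values, dtype=float)
        cal = str(ds[time].attrs.get("calendar", "gregorian"))
        return MonthlyField(
            values,
            years,
            np.asarray(ds[lat].values, dtype=float),
            np.asarray(ds[lon].values, dtype=float),
            units=str(ds[var].attrs.get("units", "")),
            calendar=cal,
        )
    finally:
        ds.close()


def write_monthly_field(field: MonthlyField, path, var: str = "field") -> None:
    """Write a MonthlyField as classic-format CF NetCDF (round-trips with
    :func:`read_monthly_field`)."""
    ny = field.years.size
    times = np.array(
        [np.datetime64(f"{y}-{m:02d}-15") for y in field.years for m in range(1, 13)]
    )
    data = field.values.reshape(ny * 12, field.lats.size, field.lons.size)
    ds = xr.Dataset(
        {var: (("time", "lat", "lon"), data, {"units": field.units})},
        coords={
            "time": ("time", times),
            "lat": ("lat", field.lats, {"units": "degrees_north"}),
            "lon": ("lon", field.lons, {"units": "degrees_east"}),
        },
    )
    ds.to_netcdf(path, engine="scipy")


def read_annual_co2_csv(path, label: str = "CO2") -> AnnualSeries:
    """Annual scalar series from a ``year,ppm`` (or generic ``year,value``) CSV."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    val = next((cols[c] for c in ("ppm", "value") if c in cols), None)
    if "year" not in cols or val is None:
        raise ValueError(f"{path}: expected columns year, ppm|value; got {list(df.columns)}")
    df = df.sort_values(cols["year"])
    return AnnualSeries(
        df[cols["year"]].to_numpy(int), df[val].to_numpy(float),
        label=label, units="ppm" if val.lower() == "ppm" else "",
    )


def write_annual_series_csv(series: AnnualSeries, path) -> None:
    pd.DataFrame({"year": series.years, "value": series.values}).to_csv(path, index=False)


def read_noaa_monthly(path, station: str | None = None) -> StationRecord:
    """Parse the NOAA/ESRL monthly text format.

    Whitespace-delimited ``site year month value`` rows; ``#`` lines are
    comments and -999.99 flags a missing month.
    """
    sites, years, months, ppm = [], [], [], []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) < 4:
                raise ValueError(f"{path}: malformed line {line!r}")
            sites.append(parts[0])
            years.append(int(parts[1]))
            months.append(int(parts[2]))
            ppm.append(float(parts[3]))
    if not years:
        raise ValueError(f"{path}: no data rows")
    vals = np.array(ppm)
    vals[np.isclose(vals, _MISSING_NOAA)] = np.nan
    return StationRecord(station or sites[0], np.array(years), np.array(months), vals)


def read_station_csv(path, station: str = "station") -> StationRecord:
    """Generic CSV dialect: columns year, month, ppm."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for need in ("year", "month", "ppm"):
        if need not in cols:
            raise ValueError(f"{path}: missing column {need!r}")
    return StationRecord(
        station,
        df[cols["year"]].to_numpy(int),
        df[cols["month"]].to_numpy(int),
        df[cols["ppm"]].to_numpy(float),
    )


def write_station_csv(rec: StationRecord, path) -> None:
    pd.DataFrame({"year": rec.year, "month": rec.month, "ppm": rec.ppm}).to_csv(
        path, index=False
    )


def read_ensemble_csv(path) -> list[EnsemblePoint]:
    """Ensemble points from CSV: member, sensitivity, sigma_b, dgpp, dgpp_sd."""
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for need in ("member", "sensitivity", "sigma_b", "dgpp", "dgpp_sd"):
        if need not in cols:
            raise ValueError(f"{path}: missing column {need!r}")
    return [
        EnsemblePoint(
            str(row[cols["member"]]),
            float(row[cols["sensitivity"]]),
            float(row[cols["sigma_b"]]),
            float(row[cols["dgpp"]]),
            float(row[cols["dgpp_sd"]]),
        )
        for _, row in df.iterrows()
    ]


def write_ensemble_csv(points, path) -> None:
    pd.DataFrame(
        {
            "member": [p.member for p in points],
            "sensitivity": [p.sensitivity for p in points],
            "sigma_b": [p.sensitivity_se for p in points],
            "dgpp": [p.dgpp for p in points],
            "dgpp_sd": [p.dgpp_sd for p in points],
        }
    ).to_csv(path, index=False)


def write_result_json(result: ConstraintResult, path, extra: dict | None = None) -> None:
    """Serialize a ConstraintResult (grids included) plus provenance extras."""
    payload = {
        "posterior_mean": result.posterior_mean,
        "posterior_sd": result.posterior_sd,
        "ensemble_mean": result.ensemble_mean,
        "ensemble_sd": result.ensemble_sd,
        "observation": {"mean": result.observation.mean, "sd": result.observation.sd},
        "raw_integral": result.raw_integral,
        "y_grid": result.y_grid.tolist(),
        "posterior": result.posterior.tolist(),
    }
    if extra:
        payload.update(extra)
    Path(path).write_text(json.dumps(payload, indent=2))
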