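"""Reading raw monthly GCM series and preparing long-term climatologies.

GCM archives deliver monthly time series (often centuries long, on 360-day
calendars, with temperatures in Kelvin and precipitation as a flux in
kg m-2 s-1). This module forms the long-term monthly mean over all available
years and converts units to degrees Celsius and total mm per month, using a
30-day month (the 360-day-calendar convention) unless physical month lengths
are requested.

Longitudes are normalized to [-180, 180) and latitudes stored ascending on
read, so every GCM arrives in one canonical orientation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import xarray as xr

from .fields import MonthlyClimateField, grid_from_coords
from .grid import GridSpec

__all__ = ["RawMonthlySeries", "long_term_monthly_mean", "convert_units", "read_monthly_series"]

logger = logging.getLogger(__name__)

SECONDS_PER_30DAY_MONTH = 60 * 60 * 24 * 30  # 2,592,000
PHYSICAL_MONTH_DAYS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31], dtype=float)

TEMPERATURE_UNITS = {"K", "Kelvin", "degC"}
PRECIP_UNITS = {"kg m-2 s-1", "mm m-2 s-1", "mm s-1", "mm month-1"}
FLUX_UNITS = PRECIP_UNITS - {"mm month-1"}


@dataclass
class RawMonthlySeries:
    """A time-ordered monthly series (length = 12 * n_years) for one
    variable of one GCM run."""

    values: np.ndarray  # (n_months, n_lat, n_lon)
    variable: str
    units: str
    grid: GridSpec
    calendar: str = "360_day"
    model_id: str = ""
    scenario: str = ""
    ensemble_member: str = "r1i1p1"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError("values must be (n_months, n_lat, n_lon)")
        if self.values.shape[0] % 12 != 0:
            raise ValueError(
                f"series length {self.values.shape[0]} is not divisible by 12"
            )
        fam_temp = self.variable in ("tas", "tasmax", "tasmin")
        if fam_temp and self.units not in TEMPERATURE_UNITS:
            raise ValueError(f"units {self.units!r} do not match variable {self.variable!r}")
        if self.variable == "pr" and self.units not in PRECIP_UNITS:
            raise ValueError(f"units {self.units!r} do not match variable 'pr'")

    @property
    def n_years(self) -> int:
        return self.values.shape[0] // 12


def long_term_monthly_mean(series: RawMonthlySeries) -> MonthlyClimateField:
    """Average each calendar month over all years of the series.

    Missing values are skipped; a cell-month is masked only when no year
    contributes data.
    """
    n = series.values.shape[0]
    if n < 12:
        raise ValueError("need at least one full year")
    byyear = series.values.reshape(series.n_years, 12, *series.values.shape[1:])
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        mean = np.nanmean(byyear, axis=0)
    logger.info(
        "long-term mean: %s %s %s over %d years",
        series.model_id, series.scenario, series.variable, series.n_years,
    )
    return MonthlyClimateField(
        data=mean,
        grid=series.grid,
        variable=series.variable,
        units=series.units,
        scenario=series.scenario,
        model_id=series.model_id,
    )


def convert_units(
    fld: MonthlyClimateField,
    use_physical_calendar: bool = False,
) -> MonthlyClimateField:
    """Convert Kelvin to degrees Celsius and precipitation flux to mm/month.

    The flux conversion multiplies by the seconds of a 30-day month
    (2,592,000), the 360-day-calendar convention, applied uniformly.
    ``use_physical_calendar=True`` uses real month lengths instead. Fields
    already in target units are returned unchanged.
    """
    if fld.units == "degC" or fld.units == "mm month-1":
        return fld
    if fld.units in ("K", "Kelvin"):
        out = fld.with_data(fld.data - 273.15, units="degC")
        logger.info("converted %s %s: K -> degC", fld.model_id, fld.variable)
        return out
    if fld.units in FLUX_UNITS:
        finite = fld.data[np.isfinite(fld.data)]
        if finite.size and finite.min() < 0:
            raise ValueError("negative precipitation flux: corrupt input")
        if use_physical_calendar:
            factor = (PHYSICAL_MONTH_DAYS * 86400.0)[:, None, None]
        else:
            factor = float(SECONDS_PER_30DAY_MONTH)
        out = fld.with_data(fld.data * factor, units="mm month-1")
        logger.info("converted %s pr: flux -> mm/month", fld.model_id)
        return out
    raise ValueError(f"unknown units tag {fld.units!r}")


def _normalize_orientation(da: xr.DataArray) -> xr.DataArray:
    """Longitudes to [-180, 180) and latitudes ascending."""
    lon = np.asarray(da["lon"])
    if lon.max() > 180.0:
        wrapped = ((lon + 180.0) % 360.0) - 180.0
        da = da.assign_coords(lon=wrapped).sortby("lon")
    lat = np.asarray(da["lat"])
    if lat.size > 1 and lat[0] > lat[-1]:
        da = da.sortby("lat")
    return da


def read_monthly_series(
    path: str | Path,
    variable: str,
    model_id: str = "",
    scenario: str = "",
) -> RawMonthlySeries:
    """Read one variable's monthly time series from a CF-style netCDF file."""
    with xr.open_dataset(path, engine="scipy", decode_times=False) as ds:
        da = _normalize_orientation(ds[variable].load())
        units = str(da.attrs.get("units", ""))
        calendar = str(ds.attrs.get("calendar", da.attrs.get("calendar", "360_day")))
        model_id = model_id or str(ds.attrs.get("model_id", ""))
        scenario = scenario or str(ds.attrs.get("scenario", ""))
        member = str(ds.attrs.get("ensemble_member", "r1i1p1"))
    grid = grid_from_coords(np.asarray(da["lon"]), np.asarray(da["lat"]))
    values = np.asarray(da.transpose("time", "lat", "lon"), dtype=float)
    return RawMonthlySeries(
        values=values,
        variable=variable,
        units=units,
        grid=grid,
        calendar=calendar,
        model_id=model_id,
        scenario=scenario,
        ensemble_member=member,
    )
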