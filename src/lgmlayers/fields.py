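"""Monthly climatology container and its netCDF representation.

A :class:`MonthlyClimateField` holds one variable's 12 monthly long-term-mean
layers for one GCM and one scenario, on a regular lon/lat grid. Missing cells
are NaN. Files are written as CF-style netCDF (dims ``time=12, lat, lon``)
through xarray's scipy backend.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import xarray as xr

from .grid import GridSpec

__all__ = ["MonthlyClimateField", "VARIABLES", "TEMPERATURE_VARIABLES"]

VARIABLES = ("pr", "tas", "tasmax", "tasmin")
TEMPERATURE_VARIABLES = ("tas", "tasmax", "tasmin")


@dataclass
class MonthlyClimateField:
    """12 monthly grids of one climate variable.

    ``data`` has shape (12, n_lat, n_lon) with latitude ascending; NaN marks
    masked cells.
    """

    data: np.ndarray
    grid: GridSpec
    variable: str
    units: str
    scenario: str = ""
    model_id: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3 or self.data.shape[0] != 12:
            raise ValueError(f"data must be (12, n_lat, n_lon), got {self.data.shape}")
        if self.data.shape[1:] != self.grid.shape:
            raise ValueError(
                f"data shape {self.data.shape[1:]} does not match grid {self.grid.shape}"
            )
        if self.variable == "pr" and self.units == "mm month-1":
            valid = self.data[np.isfinite(self.data)]
            if valid.size and valid.min() < -1e-9:
                raise ValueError("precipitation field has negative values")

    # -- convenience -------------------------------------------------------

    def with_data(self, data: np.ndarray, **changes) -> "MonthlyClimateField":
        return replace(self, data=data, **changes)

    def annual_mean(self) -> np.ndarray:
        """Mean over the 12 months, per cell (NaN if any month is missing)."""
        return self.data.mean(axis=0)

    def annual_total(self) -> np.ndarray:
        return self.data.sum(axis=0)

    # -- I/O ---------------------------------------------------------------

    def to_dataset(self) -> xr.Dataset:
        da = xr.DataArray(
            self.data,
            dims=("time", "lat", "lon"),
            coords={
                "time": np.arange(1, 13),
                "lat": self.grid.lat_centers,
                "lon": self.grid.lon_centers,
            },
            name=self.variable,
            attrs={"units": self.units},
        )
        ds = da.to_dataset()
        ds.attrs.update(
            {
                "scenario": self.scenario,
                "model_id": self.model_id,
                "resolution_deg": self.grid.resolution_deg,
                **self.attrs,
            }
        )
        return ds

    def to_netcdf(self, path: str | Path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset, variable: str | None = None) -> "MonthlyClimateField":
        if variable is None:
            candidates = [v for v in ds.data_vars if v in VARIABLES]
            if len(candidates) != 1:
                raise ValueError(f"cannot infer variable from {list(ds.data_vars)}")
            variable = candidates[0]
        da = ds[variable]
        grid = grid_from_coords(np.asarray(da["lon"]), np.asarray(da["lat"]))
        data = np.asarray(da.transpose("time", "lat", "lon"), dtype=float)
        lat = np.asarray(da["lat"])
        if lat[0] > lat[-1]:  # store latitude ascending
            data = data[:, ::-1, :]
        return cls(
            data=data,
            grid=grid,
            variable=str(variable),
            units=str(da.attrs.get("units", "")),
            scenario=str(ds.attrs.get("scenario", "")),
            model_id=str(ds.attrs.get("model_id", "")),
        )

    @classmethod
    def from_netcdf(cls, path: str | Path, variable: str | None = None) -> "MonthlyClimateField":
        with xr.open_dataset(path, engine="scipy") as ds:
            return cls.from_dataset(ds.load(), variable)


def grid_from_coords(lon: np.ndarray, lat: np.ndarray) -> GridSpec:
    """Recover a :class:`GridSpec` from cell-center coordinate vectors."""
    lon = np.sort(np.asarray(lon, dtype=float))
    lat = np.sort(np.asarray(lat, dtype=float))
    res_lon = np.diff(lon)
    res_lat = np.diff(lat)
    if lon.size > 1 and np.ptp(res_lon) > 1e-6:
        raise ValueError("longitude spacing is not uniform")
    if lat.size > 1 and np.ptp(res_lat) > 1e-6:
        raise ValueError("latitude spacing is not uniform")
    res = float(res_lon[0]) if lon.size > 1 else float(res_lat[0])
    return GridSpec(
        resolution_deg=res,
        lon_bounds=(float(lon[0] - res / 2), float(lon[-1] + res / 2)),
        lat_bounds=(float(lat[0] - res / 2), float(lat[-1] + res / 2)),
    )


def require_same_grid(a: MonthlyClimateField, b: MonthlyClimateField) -> None:
    if a.grid != b.grid:
        raise ValueError("fields are on different grids")
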