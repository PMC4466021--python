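"""The 19 bioclimatic variables (BIO1-BIO19) from monthly climatologies.

Inputs are the four downscaled monthly variables (tas, tasmax, tasmin in
degrees Celsius; pr in mm/month). Definitions follow the standard bioclim
equations, with one deliberate deviation: BIO1 is the annual mean of the
GCM's own mean-temperature field (tas), not the midpoint of tasmax and
tasmin.

A "quarter" is any window of three consecutive calendar months, with
December-January wrap-around; ties between windows are broken by the
earliest start month. BIO4 uses the sample standard deviation (ddof=1) and
BIO15 the sample coefficient of variation with a +1 mm offset in the
denominator (safe in deserts); both are switchable and recorded in the
output metadata.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import xarray as xr

from .fields import MonthlyClimateField
from .grid import GridSpec

__all__ = ["BioclimStack", "QuarterIndex", "select_quarter", "compute_bioclim", "BIO_NAMES"]

BIO_NAMES = tuple(f"BIO{i}" for i in range(1, 20))

BIO_UNITS = {
    "BIO1": "degC", "BIO2": "degC", "BIO3": "unitless x100", "BIO4": "degC x100",
    "BIO5": "degC", "BIO6": "degC", "BIO7": "degC", "BIO8": "degC", "BIO9": "degC",
    "BIO10": "degC", "BIO11": "degC", "BIO12": "mm", "BIO13": "mm", "BIO14": "mm",
    "BIO15": "percent", "BIO16": "mm", "BIO17": "mm", "BIO18": "mm", "BIO19": "mm",
}

TEMPERATURE_BIOS = tuple(f"BIO{i}" for i in range(1, 12))
PRECIPITATION_BIOS = tuple(f"BIO{i}" for i in range(12, 20))

_CRITERIA = ("wettest", "driest", "warmest", "coldest")


@dataclass(frozen=True)
class QuarterIndex:
    """A selected 3-month window (1-based start month, wrap-around allowed)."""

    start_month: int
    criterion: str

    def months(self) -> tuple[int, int, int]:
        return tuple((self.start_month - 1 + k) % 12 + 1 for k in range(3))


def _window_stack(monthly: np.ndarray, stat: str) -> np.ndarray:
    """Stat of each of the 12 wrap-around 3-month windows, stacked on axis 0.

    monthly has shape (12, ...); output (12, ...) where entry s is the
    sum/mean over months s, s+1, s+2 (mod 12).
    """
    windows = monthly + np.roll(monthly, -1, axis=0) + np.roll(monthly, -2, axis=0)
    if stat == "sum":
        return windows
    if stat == "mean":
        return windows / 3.0
    raise ValueError(stat)


def select_quarter(monthly, criterion: str) -> QuarterIndex:
    """Pick the extremal 3-month window of a 12-value monthly series.

    wettest/driest maximize/minimize the window precipitation sum;
    warmest/coldest maximize/minimize the window mean temperature. The series
    passed must be the criterion's driver (pr or tas). First-start-month wins
    ties (np.argmax/argmin return the first extremum).
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.shape != (12,):
        raise ValueError("select_quarter expects exactly 12 monthly values")
    if not np.isfinite(monthly).all():
        raise ValueError("non-finite monthly value")
    if criterion not in _CRITERIA:
        raise ValueError(f"criterion must be one of {_CRITERIA}")
    stat = "sum" if criterion in ("wettest", "driest") else "mean"
    w = _window_stack(monthly, stat)
    start = int(np.argmax(w) if criterion in ("wettest", "warmest") else np.argmin(w))
    return QuarterIndex(start_month=start + 1, criterion=criterion)


@dataclass
class BioclimStack:
    """The 19 bioclim layers on one grid, ordered BIO1..BIO19 on axis 0."""

    data: np.ndarray  # (19, n_lat, n_lon)
    grid: GridSpec
    model_id: str = ""
    scenario: str = ""
    attrs: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.shape != (19, *self.grid.shape):
            raise ValueError("bioclim stack must be (19, n_lat, n_lon) on its grid")

    def __getitem__(self, name: str) -> np.ndarray:
        return self.data[BIO_NAMES.index(name)]

    def to_dataset(self) -> xr.Dataset:
        coords = {"lat": self.grid.lat_centers, "lon": self.grid.lon_centers}
        ds = xr.Dataset(
            {
                name: xr.DataArray(
                    self.data[i], dims=("lat", "lon"), coords=coords,
                    attrs={"units": BIO_UNITS[name]},
                )
                for i, name in enumerate(BIO_NAMES)
            }
        )
        ds.attrs.update({"model_id": self.model_id, "scenario": self.scenario, **self.attrs})
        return ds

    def to_netcdf(self, path) -> None:
        self.to_dataset().to_netcdf(path, engine="scipy")

    @classmethod
    def from_dataset(cls, ds: xr.Dataset) -> "BioclimStack":
        from .fields import grid_from_coords

        grid = grid_from_coords(np.asarray(ds["lon"]), np.asarray(ds["lat"]))
        data = np.stack([np.asarray(ds[name]) for name in BIO_NAMES])
        return cls(
            data=data,
            grid=grid,
            model_id=str(ds.attrs.get("model_id", "")),
            scenario=str(ds.attrs.get("scenario", "")),
        )


def _take_window(values: np.ndarray, start_idx: np.ndarray) -> np.ndarray:
    """values (12, ...) evaluated at the window index chosen per cell."""
    return np.take_along_axis(values, start_idx[None], axis=0)[0]


def compute_bioclim(
    tas: MonthlyClimateField,
    tasmax: MonthlyClimateField,
    tasmin: MonthlyClimateField,
    pr: MonthlyClimateField,
    sd_ddof: int = 1,
    bio15_offset: float = 1.0,
) -> BioclimStack:
    """All 19 bioclimatic variables from the four aligned monthly fields.

    Cells with any non-finite month in a required input are NaN in the
    affected outputs; BIO3 is additionally masked where the annual range
    BIO7 is zero.
    """
    fields = {"tas": tas, "tasmax": tasmax, "tasmin": tasmin, "pr": pr}
    grid = tas.grid
    for name, f in fields.items():
        if f.grid != grid:
            raise ValueError(f"{name} is on a different grid")
        if f.variable and f.variable != name:
            raise ValueError(f"expected variable {name}, got {f.variable}")

    T, TX, TN, P = tas.data, tasmax.data, tasmin.data, pr.data
    bad = ~(np.isfinite(T) & np.isfinite(TX) & np.isfinite(TN) & np.isfinite(P)).all(axis=0)
    # selection below needs finite drivers; masked cells are stamped NaN at the end
    Tc = np.where(bad, 0.0, T)
    Pc = np.where(bad, 0.0, P)

    out = np.empty((19, *grid.shape))
    out[0] = T.mean(axis=0)  # BIO1 from tas directly
    out[1] = (TX - TN).mean(axis=0)  # BIO2
    out[3] = T.std(axis=0, ddof=sd_ddof) * 100.0  # BIO4
    out[4] = TX.max(axis=0)  # BIO5
    out[5] = TN.min(axis=0)  # BIO6
    out[6] = out[4] - out[5]  # BIO7
    with np.errstate(divide="ignore", invalid="ignore"):
        out[2] = 100.0 * out[1] / out[6]  # BIO3
    out[2] = np.where(out[6] == 0, np.nan, out[2])

    pr_windows = _window_stack(Pc, "sum")
    tas_windows = _window_stack(Tc, "mean")
    wettest = pr_windows.argmax(axis=0)
    driest = pr_windows.argmin(axis=0)
    warmest = tas_windows.argmax(axis=0)
    coldest = tas_windows.argmin(axis=0)

    out[7] = _take_window(tas_windows, wettest)  # BIO8
    out[8] = _take_window(tas_windows, driest)  # BIO9
    out[9] = _take_window(tas_windows, warmest)  # BIO10
    out[10] = _take_window(tas_windows, coldest)  # BIO11

    out[11] = P.sum(axis=0)  # BIO12
    out[12] = P.max(axis=0)  # BIO13
    out[13] = P.min(axis=0)  # BIO14
    out[14] = 100.0 * P.std(axis=0, ddof=sd_ddof) / (bio15_offset + P.mean(axis=0))  # BIO15
    out[15] = _take_window(pr_windows, wettest)  # BIO16
    out[16] = _take_window(pr_windows, driest)  # BIO17
    out[17] = _take_window(pr_windows, warmest)  # BIO18
    out[18] = _take_window(pr_windows, coldest)  # BIO19

    out[:, bad] = np.nan
    return BioclimStack(
        data=out,
        grid=grid,
        model_id=tas.model_id,
        scenario=tas.scenario,
        attrs={"sd_ddof": sd_ddof, "bio15_offset": bio15_offset},
    )
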