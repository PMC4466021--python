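"""Between-GCM agreement statistics per grid cell.

Given aligned bioclim stacks for several models, this module computes the
per-cell ensemble spread (sample standard deviation across models), the
quartile coefficient of dispersion QCD = (q3 - q1) / (q3 + q1) as a relative
spread measure, an all-variables agreement mask, and latitude-band / region
summaries.

QCD is only meaningful on a ratio scale: absolute-temperature variables
(BIO1, BIO5, BIO6, BIO8-BIO11) are shifted from Celsius to Kelvin before the
quartiles are taken, since quartiles straddling 0 degC make the denominator
arbitrary. Range- and ratio-type variables (BIO2-BIO4, BIO7) and all
precipitation variables are nonnegative and are used as-is. Quartiles use
linear interpolation of order statistics (the common "type 7" estimator).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import xarray as xr

from .bioclim import BIO_NAMES, BioclimStack
from .grid import GridSpec

__all__ = [
    "EnsembleCube",
    "ensemble_sd",
    "ensemble_qcd",
    "agreement_mask",
    "zonal_profile",
    "region_summary",
    "QCD_SHIFT_K",
    "ABSOLUTE_TEMPERATURE_BIOS",
]

QCD_SHIFT_K = 273.15
ABSOLUTE_TEMPERATURE_BIOS = ("BIO1", "BIO5", "BIO6", "BIO8", "BIO9", "BIO10", "BIO11")


@dataclass
class EnsembleCube:
    """Aligned {variable x model x cell} array of bioclim layers."""

    data: xr.DataArray  # dims ("variable", "model", "lat", "lon")
    grid: GridSpec

    def __post_init__(self) -> None:
        if tuple(self.data.dims) != ("variable", "model", "lat", "lon"):
            raise ValueError("cube dims must be (variable, model, lat, lon)")
        if self.data.sizes["model"] < 2:
            raise ValueError("an ensemble needs at least 2 models")

    @classmethod
    def from_stacks(cls, stacks: dict[str, BioclimStack]) -> "EnsembleCube":
        models = list(stacks)
        grids = {s.grid for s in stacks.values()}
        if len(grids) != 1:
            raise ValueError("all stacks must share one grid")
        grid = grids.pop()
        arr = np.stack([stacks[m].data for m in models], axis=1)  # (19, M, ny, nx)
        da = xr.DataArray(
            arr,
            dims=("variable", "model", "lat", "lon"),
            coords={
                "variable": list(BIO_NAMES),
                "model": models,
                "lat": grid.lat_centers,
                "lon": grid.lon_centers,
            },
        )
        return cls(data=da, grid=grid)

    @property
    def models(self) -> list[str]:
        return [str(m) for m in self.data["model"].values]

    @property
    def variables(self) -> list[str]:
        return [str(v) for v in self.data["variable"].values]

    def layer(self, variable: str, model: str) -> np.ndarray:
        return np.asarray(self.data.sel(variable=variable, model=model))


def _values(cube: EnsembleCube, variable: str) -> np.ndarray:
    """(n_models, n_lat, n_lon) slab for one variable."""
    return np.asarray(cube.data.sel(variable=variable))


def ensemble_sd(cube: EnsembleCube, variable: str, ddof: int = 1) -> xr.DataArray:
    """Per-cell sample standard deviation across models.

    Cells with fewer than 2 contributing models are NaN; cells with missing
    models use the available subset.
    """
    v = _values(cube, variable)
    n = np.isfinite(v).sum(axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        sd = np.nanstd(v, axis=0, ddof=ddof)
    sd = np.where(n >= 2, sd, np.nan)
    return xr.DataArray(
        sd,
        dims=("lat", "lon"),
        coords={"lat": cube.grid.lat_centers, "lon": cube.grid.lon_centers},
        name=f"sd_{variable}",
        attrs={"ddof": ddof, "n_models": cube.data.sizes["model"]},
    )


def ensemble_qcd(cube: EnsembleCube, variable: str, min_models: int = 4) -> xr.DataArray:
    """Per-cell quartile coefficient of dispersion (q3 - q1)/(q3 + q1).

    Absolute-temperature variables are shifted to Kelvin first. Cells with
    fewer than ``min_models`` models, or a nonpositive shifted denominator,
    are NaN; the number of masked-denominator cells is recorded in attrs.
    """
    v = _values(cube, variable)
    shift = QCD_SHIFT_K if variable in ABSOLUTE_TEMPERATURE_BIOS else 0.0
    v = v + shift
    n = np.isfinite(v).sum(axis=0)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore", category=RuntimeWarning)
        q1, q3 = np.nanpercentile(v, [25, 75], axis=0, method="linear")
    denom = q3 + q1
    with np.errstate(divide="ignore", invalid="ignore"):
        qcd = (q3 - q1) / denom
    bad_denom = np.isfinite(denom) & (denom <= 0)
    qcd = np.where((n >= min_models) & ~bad_denom, qcd, np.nan)
    return xr.DataArray(
        qcd,
        dims=("lat", "lon"),
        coords={"lat": cube.grid.lat_centers, "lon": cube.grid.lon_centers},
        name=f"qcd_{variable}",
        attrs={
            "shift": shift,
            "quartile_method": "linear (type 7)",
            "n_masked_denominator": int(bad_denom.sum()),
        },
    )


def agreement_mask(
    qcd_maps: dict[str, xr.DataArray],
    threshold: float = 0.5,
) -> xr.DataArray:
    """Cells where every variable's QCD is below the threshold.

    Expects one QCD map per bioclim variable. Output values: 1 = agree,
    0 = disagree, 255 = undefined (some variable masked there).
    """
    missing = [v for v in BIO_NAMES if v not in qcd_maps]
    if missing:
        raise ValueError(f"missing QCD maps for {missing}")
    stack = np.stack([np.asarray(qcd_maps[v]) for v in BIO_NAMES])
    defined = np.isfinite(stack).all(axis=0)
    agree = (stack < threshold).all(axis=0)
    out = np.where(defined, agree.astype(np.uint8), np.uint8(255))
    template = qcd_maps[BIO_NAMES[0]]
    return xr.DataArray(
        out, dims=("lat", "lon"), coords=template.coords,
        name="agreement", attrs={"threshold": threshold},
    )


def zonal_profile(map2d: xr.DataArray, band_width_deg: float = 5.0) -> pd.Series:
    """Latitude-band means of a map, ordered south to north.

    Empty bands are NaN. The index holds band-center latitudes.
    """
    lat = np.asarray(map2d["lat"])
    values = np.asarray(map2d)
    edges = np.arange(-90.0, 90.0 + band_width_deg / 2, band_width_deg)
    centers = (edges[:-1] + edges[1:]) / 2
    which = np.clip(np.digitize(lat, edges) - 1, 0, len(centers) - 1)
    out = np.full(len(centers), np.nan)
    for b in range(len(centers)):
        rows = which == b
        if rows.any():
            vals = values[rows]
            vals = vals[np.isfinite(vals)]
            if vals.size:
                out[b] = vals.mean()
    return pd.Series(out, index=pd.Index(centers, name="lat_band_center"), name=map2d.name)


def region_summary(map2d: xr.DataArray, region_mask: np.ndarray) -> pd.DataFrame:
    """Per-region mean, SD and cell count of a map.

    ``region_mask`` is an integer label grid aligned to the map; labels with
    zero unmasked cells are reported with n_cells = 0.
    """
    labels = np.asarray(region_mask)
    values = np.asarray(map2d)
    if labels.shape != values.shape:
        raise ValueError("region mask shape does not match the map")
    rows = []
    for lab in np.unique(labels):
        vals = values[labels == lab]
        vals = vals[np.isfinite(vals)]
        rows.append(
            {
                "region": lab,
                "mean": vals.mean() if vals.size else np.nan,
                "sd": vals.std(ddof=1) if vals.size > 1 else np.nan,
                "n_cells": int(vals.size),
            }
        )
    return pd.DataFrame(rows).set_index("region")
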