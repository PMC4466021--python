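"""Regular lon/lat grids with cell-center registration.

All layers in this package live on regular equal-angle grids. A grid is
described by its resolution in decimal degrees and its outer bounds; cell
centers sit half a cell inside the bounds, so the global 0.5 degree grid has
centers at -179.75 ... 179.75 and -89.75 ... 89.75. Latitudes are stored
ascending (south to north) everywhere.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import cached_property

import numpy as np

__all__ = ["GridSpec"]


@dataclass(frozen=True)
class GridSpec:
    """A regular lon/lat grid, cell-center registered.

    Parameters
    ----------
    resolution_deg
        Cell size in decimal degrees (same for lon and lat).
    lon_bounds, lat_bounds
        Outer edges of the grid in degrees. The extent along each axis must
        be an integer multiple of the resolution.
    """

    resolution_deg: float
    lon_bounds: tuple[float, float] = (-180.0, 180.0)
    lat_bounds: tuple[float, float] = (-90.0, 90.0)

    def __post_init__(self) -> None:
        if self.resolution_deg <= 0:
            raise ValueError("resolution_deg must be positive")
        lo_lon, hi_lon = self.lon_bounds
        lo_lat, hi_lat = self.lat_bounds
        if not (-180.0 <= lo_lon < hi_lon <= 180.0):
            raise ValueError(f"invalid lon_bounds {self.lon_bounds}")
        if not (-90.0 <= lo_lat < hi_lat <= 90.0):
            raise ValueError(f"invalid lat_bounds {self.lat_bounds}")
        for lo, hi in (self.lon_bounds, self.lat_bounds):
            n = (hi - lo) / self.resolution_deg
            if abs(n - round(n)) > 1e-8:
                raise ValueError(
                    f"extent {hi - lo} not divisible by resolution {self.resolution_deg}"
                )

    @classmethod
    def global_grid(cls, resolution_deg: float) -> "GridSpec":
        return cls(resolution_deg=resolution_deg)

    @property
    def n_lon(self) -> int:
        return round((self.lon_bounds[1] - self.lon_bounds[0]) / self.resolution_deg)

    @property
    def n_lat(self) -> int:
        return round((self.lat_bounds[1] - self.lat_bounds[0]) / self.resolution_deg)

    @property
    def shape(self) -> tuple[int, int]:
        """(n_lat, n_lon) — the array shape of one layer on this grid."""
        return (self.n_lat, self.n_lon)

    @cached_property
    def lon_centers(self) -> np.ndarray:
        lo = self.lon_bounds[0]
        return lo + self.resolution_deg * (np.arange(self.n_lon) + 0.5)

    @cached_property
    def lat_centers(self) -> np.ndarray:
        """Ascending latitudes of cell centers."""
        lo = self.lat_bounds[0]
        return lo + self.resolution_deg * (np.arange(self.n_lat) + 0.5)

    def cell_centers(self) -> np.ndarray:
        """All cell centers as an (n_lat * n_lon, 2) array of (lon, lat) rows.

        Ordering is row-major over (lat, lon), matching ``layer.ravel()``.
        """
        lon2d, lat2d = np.meshgrid(self.lon_centers, self.lat_centers)
        return np.column_stack([lon2d.ravel(), lat2d.ravel()])

    def diagonal_deg(self) -> float:
        """Length of the domain diagonal in degree space."""
        dx = self.lon_bounds[1] - self.lon_bounds[0]
        dy = self.lat_bounds[1] - self.lat_bounds[0]
        return float(np.hypot(dx, dy))

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, GridSpec):
            return NotImplemented
        return (
            abs(self.resolution_deg - other.resolution_deg) < 1e-9
            and self.lon_bounds == other.lon_bounds
            and self.lat_bounds == other.lat_bounds
        )

    def __hash__(self) -> int:
        return hash((round(self.resolution_deg, 9), self.lon_bounds, self.lat_bounds))
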