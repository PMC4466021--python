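"""Spherical variograms: sample variograms and weighted least-squares fits.

The spherical model is

    gamma(h) = nugget + psill * (1.5 h/r - 0.5 (h/r)^3)   for 0 < h < r
    gamma(h) = nugget + psill                              for h >= r
    gamma(0) = 0

with range r in degrees of the unprojected lon/lat plane. It reaches its sill
exactly at the range, matching the finite correlation lengths typical of
climate fields. Distances throughout are Euclidean in degree space, the
convention of kriging on unprojected grids; a haversine option is available
on the distance helper.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.distance import pdist

__all__ = [
    "VariogramModel",
    "SampleVariogram",
    "empirical_variogram",
    "fit_spherical_variogram",
]

EARTH_RADIUS_KM = 6371.0


def pairwise_distances(xy: np.ndarray, metric: str = "euclidean") -> np.ndarray:
    """Condensed pairwise distances between (lon, lat) rows.

    metric="euclidean" treats degrees as planar coordinates (the default
    convention of this package); metric="haversine" returns great-circle
    distances in km.
    """
    if metric == "euclidean":
        return pdist(xy)
    if metric == "haversine":
        rad = np.radians(xy)

        def hav(u, v):
            dlon, dlat = v - u
            a = np.sin(dlat / 2) ** 2 + np.cos(u[1]) * np.cos(v[1]) * np.sin(dlon / 2) ** 2
            return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(a))

        return pdist(rad, hav)
    raise ValueError(f"unknown metric {metric!r}")


@dataclass(frozen=True)
class VariogramModel:
    """Fitted spherical variogram (nugget, partial sill, range in degrees)."""

    nugget: float
    partial_sill: float
    range_deg: float
    converged: bool = True
    residual_norm: float = 0.0

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.partial_sill < 0:
            raise ValueError("partial sill must be >= 0")
        if self.range_deg <= 0:
            raise ValueError("range must be > 0")

    @property
    def sill(self) -> float:
        return self.nugget + self.partial_sill

    @property
    def is_degenerate(self) -> bool:
        """True when the model carries no structure (flat field)."""
        return self.sill < 1e-12

    def gamma(self, h: np.ndarray | float) -> np.ndarray:
        """Semivariance at lag h (gamma(0) = 0 by convention)."""
        h = np.asarray(h, dtype=float)
        hr = np.clip(h / self.range_deg, 0.0, 1.0)
        g = self.nugget + self.partial_sill * (1.5 * hr - 0.5 * hr**3)
        return np.where(h > 0, g, 0.0)

    def covariance(self, h: np.ndarray | float) -> np.ndarray:
        """Stationary covariance C(h) = sill - gamma(h), nugget at h = 0 only."""
        h = np.asarray(h, dtype=float)
        hr = np.clip(h / self.range_deg, 0.0, 1.0)
        c = self.partial_sill * (1.0 - 1.5 * hr + 0.5 * hr**3)
        return np.where(h > 0, c, self.partial_sill + self.nugget)


@dataclass
class SampleVariogram:
    """Binned omnidirectional sample variogram.

    ``lags`` are bin centers (degrees), ``semivariance`` the mean of
    0.5*(z_i - z_j)^2 over pairs in each bin, ``counts`` the pair counts.
    Only nonempty bins are kept.
    """

    lags: np.ndarray
    semivariance: np.ndarray
    counts: np.ndarray
    n_points: int | None = None

    def __post_init__(self) -> None:
        self.lags = np.asarray(self.lags, dtype=float)
        self.semivariance = np.asarray(self.semivariance, dtype=float)
        self.counts = np.asarray(self.counts, dtype=int)
        if not (self.lags.shape == self.semivariance.shape == self.counts.shape):
            raise ValueError("lags, semivariance and counts must be the same length")
        if (self.semivariance < 0).any():
            raise ValueError("semivariance must be >= 0")
        if (self.counts < 1).any():
            raise ValueError("reported bins must contain at least one pair")

    @property
    def n_bins(self) -> int:
        return int(self.lags.size)


def empirical_variogram(
    xy: np.ndarray,
    values: np.ndarray,
    n_bins: int = 15,
    cutoff: float | None = None,
    max_points: int | None = 3000,
    seed: int = 0,
    metric: str = "euclidean",
) -> SampleVariogram:
    """Binned omnidirectional sample variogram of scattered observations.

    Parameters
    ----------
    xy
        (n, 2) array of (lon, lat) observation locations.
    values
        Observation values, shape (n,).
    n_bins
        Number of equal-width lag bins.
    cutoff
        Maximum lag considered; defaults to one third of the bounding-box
        diagonal (the gstat convention).
    max_points
        Pairwise semivariances grow quadratically; above this many points a
        seeded random subsample is used. None disables subsampling.
    """
    xy = np.asarray(xy, dtype=float)
    values = np.asarray(values, dtype=float)
    ok = np.isfinite(values)
    xy, values = xy[ok], values[ok]
    n = len(values)
    if n < 2:
        raise ValueError("at least 2 points are required for a sample variogram")
    n_total = n
    if max_points is not None and n > max_points:
        rng = np.random.default_rng(seed)
        keep = rng.choice(n, size=max_points, replace=False)
        keep.sort()
        xy, values = xy[keep], values[keep]
        n = max_points

    d = pairwise_distances(xy, metric=metric)
    sv = 0.5 * pdist(values[:, None], metric="sqeuclidean")
    if cutoff is None:
        span = xy.max(axis=0) - xy.min(axis=0)
        cutoff = float(np.hypot(*span)) / 3.0
        if cutoff <= 0:
            cutoff = float(d.max()) or 1.0
    inside = (d > 0) & (d <= cutoff)
    d, sv = d[inside], sv[inside]
    if d.size == 0:
        raise ValueError("no point pairs within the cutoff distance")

    edges = np.linspace(0.0, cutoff, n_bins + 1)
    which = np.clip(np.digitize(d, edges) - 1, 0, n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    sums = np.bincount(which, weights=sv, minlength=n_bins)
    dsums = np.bincount(which, weights=d, minlength=n_bins)
    nonempty = counts > 0
    return SampleVariogram(
        lags=dsums[nonempty] / counts[nonempty],
        semivariance=sums[nonempty] / counts[nonempty],
        counts=counts[nonempty],
        n_points=n_total,
    )


def _spherical(h: np.ndarray, nugget: float, psill: float, rng: float) -> np.ndarray:
    hr = np.clip(h / rng, 0.0, 1.0)
    return nugget + psill * (1.5 * hr - 0.5 * hr**3)


def fit_spherical_variogram(
    sample: SampleVariogram,
    min_points: int = 30,
) -> VariogramModel:
    """Fit a spherical model to a sample variogram by weighted least squares.

    Weights are N_h / h^2 (pair count over squared lag), which favours the
    short lags that dominate kriging weights. Bounds keep nugget and partial
    sill nonnegative and the range positive. On optimizer failure the
    method-of-moments initial estimate is returned with ``converged=False``
    rather than failing silently.
    """
    if sample.n_bins < 3:
        raise ValueError(f"need >= 3 nonempty bins to fit, got {sample.n_bins}")
    if sample.n_points is not None and sample.n_points < min_points:
        raise ValueError(
            f"refusing to fit a variogram from {sample.n_points} points (< {min_points})"
        )
    h, g, n = sample.lags, sample.semivariance, sample.counts
    w = np.sqrt(n / np.maximum(h, 1e-12) ** 2)

    gmax = float(g.max())
    if gmax < 1e-15:  # flat field: pure-nugget degenerate structure
        return VariogramModel(
            nugget=0.0,
            partial_sill=0.0,
            range_deg=float(h[0]),
            converged=False,
            residual_norm=0.0,
        )

    nugget0 = max(float(g[0]) - 0.5 * (float(g[1]) - float(g[0])), 0.0)
    nugget0 = min(nugget0, gmax)
    psill0 = max(gmax - nugget0, 1e-12 * gmax + 1e-30)
    reach = np.nonzero(g >= nugget0 + 0.95 * psill0)[0]
    range0 = float(h[reach[0]]) if reach.size else float(h[-1])
    range0 = max(range0, float(h[0]))
    x0 = np.array([nugget0, psill0, range0])

    def resid(x):
        return w * (_spherical(h, *x) - g)

    try:
        fit = least_squares(
            resid,
            x0,
            bounds=([0.0, 0.0, 1e-9], [np.inf, np.inf, np.inf]),
            x_scale=np.maximum(np.abs(x0), [gmax, gmax, float(h[-1])]),
        )
        ok = fit.success
        x = fit.x
        rnorm = float(np.linalg.norm(fit.fun))
    except Exception:
        ok = False
        x = x0
        rnorm = float(np.linalg.norm(resid(x0)))
    if not ok:
        x = x0
        rnorm = float(np.linalg.norm(resid(x0)))
    return VariogramModel(
        nugget=float(x[0]),
        partial_sill=float(x[1]),
        range_deg=float(max(x[2], 1e-9)),
        converged=bool(ok),
        residual_norm=rnorm,
    )
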