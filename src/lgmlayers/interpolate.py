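"""Spatial interpolators: ordinary kriging and the comparison methods.

Ordinary kriging solves, for each prediction point, the (k+1)-dimensional
linear system

    | Gamma  1 | | lambda |   | gamma0 |
    | 1^T    0 | |   mu   | = |   1    |

over its k = 12 nearest observations, where Gamma holds pairwise
semivariances, gamma0 the semivariances to the target, and the Lagrange
multiplier mu enforces sum(lambda) = 1 (unbiasedness). The prediction is
sum(lambda_i z_i). Systems are assembled and solved in batches.

Comparison methods mirror a standard interpolation sensitivity analysis:
inverse distance weighting (power 2, same 12-neighbor stencil), thin-plate
splines (scipy RBF, local neighborhood), and a 12th-degree trend surface
(orthogonalized bivariate Legendre basis; raw monomials of that degree are
numerically unusable). Natural neighbor has no robust implementation in the
supported stack and is feature-flagged off.

Distances are Euclidean in degree space on (lon, lat) — the behaviour of
kriging toolchains on unprojected coordinates. Nearest-neighbor ties are
broken by (lat, lon) lexicographic order of the observations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.interpolate import RBFInterpolator
from scipy.spatial import cKDTree

from .grid import GridSpec
from .variogram import VariogramModel

__all__ = [
    "krige_to_grid",
    "krige_points",
    "interpolate_alternative",
    "AVAILABLE_METHODS",
    "KrigingReport",
]

AVAILABLE_METHODS = ("kriging", "idw", "thin_plate_spline", "trend_surface_deg12")

_BATCH = 20000


@dataclass
class KrigingReport:
    n_masked: int = 0
    n_deduplicated: int = 0
    degenerate_model: bool = False


def _prepare_observations(points: np.ndarray, values: np.ndarray):
    """Drop NaNs, enforce deterministic (lat, lon) order, average duplicates."""
    points = np.asarray(points, dtype=float)
    values = np.asarray(values, dtype=float).ravel()
    ok = np.isfinite(values) & np.isfinite(points).all(axis=1)
    points, values = points[ok], values[ok]
    order = np.lexsort((points[:, 0], points[:, 1]))  # by (lat, lon)
    points, values = points[order], values[order]
    uniq, inverse = np.unique(points, axis=0, return_inverse=True)
    n_dup = len(points) - len(uniq)
    if n_dup:
        sums = np.bincount(inverse, weights=values, minlength=len(uniq))
        counts = np.bincount(inverse, minlength=len(uniq))
        values = sums / counts
        order = np.lexsort((uniq[:, 0], uniq[:, 1]))
        points, values = uniq[order], values[order]
    return points, values, n_dup


def _as_query_points(target: GridSpec | np.ndarray) -> np.ndarray:
    if isinstance(target, GridSpec):
        return target.cell_centers()
    return np.asarray(target, dtype=float)


def krige_points(
    points: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    query: np.ndarray,
    n_neighbors: int = 12,
    report: KrigingReport | None = None,
) -> np.ndarray:
    """Ordinary-kriging predictions at arbitrary query locations."""
    points, values, n_dup = _prepare_observations(points, values)
    if report is not None:
        report.n_deduplicated = n_dup
    if len(points) < 1:
        raise ValueError("no valid observations")
    k = min(n_neighbors, len(points))
    tree = cKDTree(points)
    query = np.asarray(query, dtype=float)
    dist, idx = tree.query(query, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]

    if model.is_degenerate:
        # Pure-nugget / flat-field limit of OK: equal weights over neighbors.
        if report is not None:
            report.degenerate_model = True
        return values[idx].mean(axis=1)

    out = np.empty(len(query))
    n_masked = 0
    for lo in range(0, len(query), _BATCH):
        sl = slice(lo, lo + _BATCH)
        nb = points[idx[sl]]  # (B, k, 2)
        z = values[idx[sl]]  # (B, k)
        d0 = dist[sl]  # (B, k)
        diff = nb[:, :, None, :] - nb[:, None, :, :]
        H = np.sqrt((diff**2).sum(-1))
        B = len(z)
        A = np.empty((B, k + 1, k + 1))
        A[:, :k, :k] = model.gamma(H)
        A[:, k, :k] = 1.0
        A[:, :k, k] = 1.0
        A[:, k, k] = 0.0
        b = np.empty((B, k + 1, 1))
        b[:, :k, 0] = model.gamma(d0)
        b[:, k, 0] = 1.0
        try:
            lam = np.linalg.solve(A, b)[:, :k, 0]
            pred = (lam * z).sum(axis=1)
        except np.linalg.LinAlgError:
            pred = np.empty(B)
            for i in range(B):
                try:
                    lam_i = np.linalg.solve(A[i], b[i])[:k, 0]
                    pred[i] = lam_i @ z[i]
                except np.linalg.LinAlgError:
                    pred[i] = np.nan
                    n_masked += 1
        out[sl] = pred
    if report is not None:
        report.n_masked = n_masked
    return out


def krige_to_grid(
    points: np.ndarray,
    values: np.ndarray,
    model: VariogramModel,
    target: GridSpec,
    n_neighbors: int = 12,
    report: KrigingReport | None = None,
) -> np.ndarray:
    """Ordinary kriging onto the cell centers of a target grid.

    Returns an (n_lat, n_lon) array; cells whose kriging system stays
    singular after duplicate-averaging are NaN and counted in ``report``.
    """
    pred = krige_points(points, values, model, _as_query_points(target), n_neighbors, report)
    return pred.reshape(target.shape)


# ---------------------------------------------------------------------------
# Alternative methods


def _idw(points, values, query, n_neighbors=12, power=2.0):
    tree = cKDTree(points)
    k = min(n_neighbors, len(points))
    dist, idx = tree.query(query, k=k)
    if k == 1:
        dist, idx = dist[:, None], idx[:, None]
    z = values[idx]
    with np.errstate(divide="ignore"):
        w = 1.0 / dist**power
    exact = dist < 1e-12
    hit = exact.any(axis=1)
    w[~np.isfinite(w)] = 0.0
    pred = (w * z).sum(axis=1) / w.sum(axis=1)
    if hit.any():
        first = exact.argmax(axis=1)
        pred[hit] = z[hit, first[hit]]
    return pred


def _thin_plate_spline(points, values, query, n_neighbors=12):
    neighbors = None if len(points) <= max(n_neighbors, 50) else n_neighbors
    rbf = RBFInterpolator(points, values, kernel="thin_plate_spline", neighbors=neighbors)
    return rbf(query)


def _trend_surface_coeff_count(degree: int) -> int:
    return (degree + 1) * (degree + 2) // 2


def _legendre_design(points, degree, lon_span, lat_span):
    # map to [-1, 1] and keep only total degree <= degree
    x = 2 * (points[:, 0] - lon_span[0]) / (lon_span[1] - lon_span[0]) - 1
    y = 2 * (points[:, 1] - lat_span[0]) / (lat_span[1] - lat_span[0]) - 1
    vx = np.polynomial.legendre.legvander(x, degree)
    vy = np.polynomial.legendre.legvander(y, degree)
    cols = [vx[:, i] * vy[:, j] for i in range(degree + 1) for j in range(degree + 1 - i)]
    return np.column_stack(cols)


def _trend_surface(points, values, query, degree=12):
    need = _trend_surface_coeff_count(degree)
    if len(points) < need:
        raise ValueError(
            f"trend surface of degree {degree} needs >= {need} points, got {len(points)}"
        )
    lon_span = (
        min(points[:, 0].min(), query[:, 0].min()),
        max(points[:, 0].max(), query[:, 0].max()),
    )
    lat_span = (
        min(points[:, 1].min(), query[:, 1].min()),
        max(points[:, 1].max(), query[:, 1].max()),
    )
    X = _legendre_design(points, degree, lon_span, lat_span)
    coef, *_ = np.linalg.lstsq(X, values, rcond=None)
    return _legendre_design(query, degree, lon_span, lat_span) @ coef


def interpolate_alternative(
    points: np.ndarray,
    values: np.ndarray,
    target: GridSpec | np.ndarray,
    method: str,
    n_neighbors: int = 12,
) -> np.ndarray:
    """Interpolate scattered observations by one of the comparison methods.

    method is one of "idw", "thin_plate_spline", "trend_surface_deg12".
    "natural_neighbor" is recognized but unavailable. Output matches the
    target grid shape (or the query point count).
    """
    if method == "natural_neighbor":
        raise NotImplementedError(
            "natural_neighbor is feature-flagged off (no robust implementation available)"
        )
    points, values, _ = _prepare_observations(points, values)
    query = _as_query_points(target)
    if method == "idw":
        pred = _idw(points, values, query, n_neighbors=n_neighbors)
    elif method == "thin_plate_spline":
        pred = _thin_plate_spline(points, values, query, n_neighbors=n_neighbors)
    elif method == "trend_surface_deg12":
        pred = _trend_surface(points, values, query, degree=12)
    else:
        raise ValueError(f"unknown interpolation method {method!r}")
    if isinstance(target, GridSpec):
        return pred.reshape(target.shape)
    return pred
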