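"""Synthetic pseudo-GCM ensembles with controlled spatial structure.

Real multi-GCM archives are hundreds of gigabytes; every downstream stage of
this package is instead exercised on synthetic ensembles that emulate the
statistical features that matter for the analysis:

* spatially autocorrelated monthly fields (stationary Gaussian random fields
  with a spherical covariance, generated by circulant embedding);
* a shared climate signal (a smooth meridional climatology plus a common
  random field) so all models correlate strongly, as real GCMs do;
* planted model groups — models in a group share a group-specific deviation
  field, models in different groups only share the common signal;
* a latitude-dependent disagreement profile: temperature disagreement grows
  toward the poles while precipitation disagreement concentrates in the
  tropics (a logistic ramp in |lat| with midpoint 35 degrees by default).

Physical ordering tasmin <= tas <= tasmax is enforced by construction
(tas +/- half of a positive diurnal-range field) and precipitation is
clipped at zero after noise is added.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from .fields import MonthlyClimateField
from .grid import GridSpec

__all__ = [
    "FieldParams",
    "EnsembleConfig",
    "PseudoGcmEnsemble",
    "generate_gaussian_field",
    "generate_pseudo_gcm_ensemble",
]

SCENARIOS = ("modern", "lgm")


# ---------------------------------------------------------------------------
# Stationary Gaussian random fields by circulant embedding


def _spherical_covariance(h: np.ndarray, psill: float, range_deg: float) -> np.ndarray:
    hr = np.clip(h / range_deg, 0.0, 1.0)
    return psill * (1.0 - 1.5 * hr + 0.5 * hr**3)


class _FieldFactory:
    """Caches the spectral square root of the embedded covariance for a
    (grid, variogram) pair so repeated draws cost one FFT each."""

    def __init__(self, grid: GridSpec, nugget: float, psill: float, range_deg: float):
        self.grid = grid
        self.nugget = float(nugget)
        self.psill = float(psill)
        ny, nx = grid.shape
        self.ny, self.nx = ny, nx
        if psill > 0:
            M, N = 2 * ny, 2 * nx
            res = grid.resolution_deg
            iy = np.minimum(np.arange(M), M - np.arange(M)) * res
            ix = np.minimum(np.arange(N), N - np.arange(N)) * res
            h = np.hypot(iy[:, None], ix[None, :])
            cov = _spherical_covariance(h, psill, range_deg)
            lam = np.fft.fft2(cov).real
            lam[lam < 0] = 0.0  # embedding may be slightly indefinite; clip
            self._sqrt_lam = np.sqrt(lam)
            self._MN = M * N
        else:
            self._sqrt_lam = None

    def draw(self, rng: np.random.Generator) -> np.ndarray:
        """One zero-mean realization with the requested covariance."""
        ny, nx = self.ny, self.nx
        if self._sqrt_lam is not None:
            M2 = self._sqrt_lam.shape
            eps = rng.standard_normal(M2) + 1j * rng.standard_normal(M2)
            f = np.fft.fft2(self._sqrt_lam * eps) / np.sqrt(self._MN)
            smooth = f.real[:ny, :nx]
        else:
            smooth = np.zeros((ny, nx))
        if self.nugget > 0:
            smooth = smooth + np.sqrt(self.nugget) * rng.standard_normal((ny, nx))
        return smooth


@dataclass(frozen=True)
class FieldParams:
    """Parameters of one synthetic monthly field: its mean level and the
    spherical-variogram triple (nugget, sill contribution, range in deg)."""

    mean: float
    nugget: float
    psill: float
    range_deg: float
    seed: int = 0

    def __post_init__(self) -> None:
        if self.nugget < 0:
            raise ValueError("nugget must be >= 0")
        if self.psill < 0:
            raise ValueError("partial sill must be >= 0")
        if self.range_deg <= 0:
            raise ValueError("range must be > 0")


def generate_gaussian_field(
    grid: GridSpec,
    params: FieldParams,
    variable: str = "tas",
    units: str = "degC",
) -> MonthlyClimateField:
    """12 independent monthly realizations of a stationary random field.

    Each month is an independent draw with the requested spherical
    covariance plus nugget, around the constant ``params.mean``.
    Deterministic given ``params.seed``.
    """
    if grid.n_lat < 4 or grid.n_lon < 4:
        raise ValueError("grid must be at least 4x4 cells")
    factory = _FieldFactory(grid, params.nugget, params.psill, params.range_deg)
    rng = np.random.default_rng(params.seed)
    data = np.stack([params.mean + factory.draw(rng) for _ in range(12)])
    return MonthlyClimateField(
        data=data, grid=grid, variable=variable, units=units,
        scenario="synthetic", model_id="synthetic",
    )


# ---------------------------------------------------------------------------
# Pseudo-GCM ensembles


def _logistic(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass(frozen=True)
class LatitudeProfile:
    """Logistic disagreement amplitude in |lat|: low near the equator and
    high poleward for temperature, reversed for precipitation."""

    low: float
    high: float
    midpoint_deg: float = 35.0
    width_deg: float = 8.0
    increasing: bool = True  # amplitude grows with |lat|

    def __post_init__(self) -> None:
        if self.low < 0 or self.high < 0:
            raise ValueError("noise amplitudes must be >= 0")

    def amplitude(self, lat: np.ndarray) -> np.ndarray:
        ramp = _logistic((np.abs(lat) - self.midpoint_deg) / self.width_deg)
        if not self.increasing:
            ramp = 1.0 - ramp
        return self.low + (self.high - self.low) * ramp


DEFAULT_GROUPS = (0, 0, 0, 1, 1, 2, 2, 3, 3)  # 9 models in 4 groups


@dataclass
class EnsembleConfig:
    """Configuration of a synthetic multi-GCM ensemble.

    Defaults mirror the real-archive study conditions: nine models, four
    planted groups, temperature disagreement ramping up poleward of ~35
    degrees and precipitation disagreement ramping down.
    """

    n_models: int = 9
    group_labels: tuple[int, ...] = DEFAULT_GROUPS
    temperature_profile: LatitudeProfile = dc_field(
        default_factory=lambda: LatitudeProfile(low=0.5, high=4.0, increasing=True)
    )
    precipitation_profile: LatitudeProfile = dc_field(
        default_factory=lambda: LatitudeProfile(low=5.0, high=50.0, increasing=False)
    )
    noise_frac: float = 0.05  # within-group model noise as a fraction of group amplitude
    range_deg: float = 25.0  # spatial range of signal/deviation fields
    lgm_cooling_degC: float = 5.0
    lgm_drying_frac: float = 0.25
    seed: int = 0
    model_seeds: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        if self.n_models < 2:
            raise ValueError("n_models must be >= 2")
        if len(self.group_labels) != self.n_models:
            raise ValueError("group labels must cover all models")
        if len(set(self.group_labels)) > self.n_models:
            raise ValueError("more groups than models")
        if self.noise_frac < 0:
            raise ValueError("noise fraction must be >= 0")

    @property
    def model_ids(self) -> list[str]:
        return [f"GCM{i:02d}" for i in range(self.n_models)]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "EnsembleConfig":
        raw = yaml.safe_load(Path(path).read_text())
        for key in ("temperature_profile", "precipitation_profile"):
            if key in raw:
                raw[key] = LatitudeProfile(**raw[key])
        for key in ("group_labels", "model_seeds"):
            if key in raw and raw[key] is not None:
                raw[key] = tuple(raw[key])
        return cls(**raw)


@dataclass
class PseudoGcmEnsemble:
    """Generated ensemble: fields[model_id][scenario][variable] plus the
    planted group labels."""

    fields: dict
    group_labels: dict  # model_id -> group index
    config: EnsembleConfig
    grid: GridSpec

    @property
    def model_ids(self) -> list[str]:
        return list(self.fields)

    def get(self, model_id: str, scenario: str, variable: str) -> MonthlyClimateField:
        return self.fields[model_id][scenario][variable]

    def to_netcdf_dir(self, directory: str | Path) -> list[Path]:
        """One CF-style file per (model, scenario), variables pr/tas/tasmax/tasmin."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        written = []
        for model_id, scenarios in self.fields.items():
            for scenario, variables in scenarios.items():
                ds = None
                for var, fld in variables.items():
                    d = fld.to_dataset()
                    ds = d if ds is None else ds.merge(d)
                ds.attrs["planted_group"] = int(self.group_labels[model_id])
                path = directory / f"{model_id}_{scenario}.nc"
                ds.to_netcdf(path, engine="scipy")
                written.append(path)
        return written


def _seasonal_cycle(lat: np.ndarray, months: np.ndarray) -> np.ndarray:
    """Signed seasonal temperature cycle: peaks in July in the north and in
    January in the south, amplitude growing with latitude."""
    amp = 12.0 * np.sin(np.radians(lat))
    phase = np.cos(2.0 * np.pi * (months[:, None, None] - 7) / 12.0)
    return amp[None, :, :] * phase


def generate_pseudo_gcm_ensemble(
    config: EnsembleConfig,
    grid: GridSpec,
) -> PseudoGcmEnsemble:
    """Generate per-model {modern, lgm} x {pr, tas, tasmax, tasmin} sets.

    Model m in planted group g is built, per month and variable, as

        common climatology + amp(lat) * (G_g + noise_frac * N_m)

    where G_g is the group deviation field, N_m the model's own noise field
    (both unit-variance, spatially correlated) and amp(lat) the
    variable-family disagreement profile. The LGM scenario applies a uniform
    cooling and a fractional drying to the shared climatology, so trends are
    well defined for the change-factor pipeline.
    """
    groups = sorted(set(config.group_labels))
    n_groups = len(groups)
    if n_groups > config.n_models:
        raise ValueError("more planted groups than models")

    ss = np.random.SeedSequence(config.seed)
    common_rng = np.random.default_rng(ss.spawn(1)[0])
    group_rngs = {g: np.random.default_rng(s) for g, s in zip(groups, ss.spawn(n_groups))}
    if config.model_seeds is not None:
        if len(config.model_seeds) != config.n_models:
            raise ValueError("model_seeds must have one entry per model")
        model_rngs = [np.random.default_rng(s) for s in config.model_seeds]
    else:
        model_rngs = [np.random.default_rng(s) for s in ss.spawn(config.n_models)]

    factory = _FieldFactory(grid, nugget=0.0, psill=1.0, range_deg=config.range_deg)
    lon2d, lat2d = np.meshgrid(grid.lon_centers, grid.lat_centers)
    months = np.arange(1, 13)

    amp_T = config.temperature_profile.amplitude(lat2d)
    amp_P = config.precipitation_profile.amplitude(lat2d)

    # Shared climatology (identical across models): meridional gradient,
    # seasonal cycle, one smooth common anomaly field per month.
    base_T = 27.0 - 45.0 * np.sin(np.radians(lat2d)) ** 2
    base_T = base_T[None] + _seasonal_cycle(lat2d, months)
    base_T = base_T + 2.0 * np.stack([factory.draw(common_rng) for _ in months])
    base_DTR = np.clip(
        8.0 + 2.0 * np.stack([factory.draw(common_rng) for _ in months]), 1.0, None
    )
    base_P = 160.0 * np.exp(-((lat2d / 25.0) ** 2)) + 30.0
    season_P = 1.0 + 0.25 * np.cos(2.0 * np.pi * (months[:, None, None] - 7) / 12.0) * np.sin(
        np.radians(lat2d)
    )
    base_P = base_P[None] * season_P + 15.0 * np.stack(
        [factory.draw(common_rng) for _ in months]
    )

    # Group deviation fields per scenario, per base variable, per month.
    def draw12(rng):
        return np.stack([factory.draw(rng) for _ in range(12)])

    group_dev = {
        g: {scen: {v: draw12(group_rngs[g]) for v in ("T", "P", "D")} for scen in SCENARIOS}
        for g in groups
    }

    fields: dict = {}
    labels: dict = {}
    for m, model_id in enumerate(config.model_ids):
        g = config.group_labels[m]
        labels[model_id] = g
        rng = model_rngs[m]
        noise = {
            scen: {v: draw12(rng) for v in ("T", "P", "D")} for scen in SCENARIOS
        }
        fields[model_id] = {}
        for scen in SCENARIOS:
            dT = amp_T[None] * (
                group_dev[g][scen]["T"] + config.noise_frac * noise[scen]["T"]
            )
            dP = amp_P[None] * (
                group_dev[g][scen]["P"] + config.noise_frac * noise[scen]["P"]
            )
            dD = 0.5 * (group_dev[g][scen]["D"] + config.noise_frac * noise[scen]["D"])
            T = base_T + dT
            P = base_P + dP
            if scen == "lgm":
                T = T - config.lgm_cooling_degC
                P = P * (1.0 - config.lgm_drying_frac)
            P = np.clip(P, 0.0, None)
            half = 0.5 * np.clip(base_DTR + dD, 1.0, None)
            fields[model_id][scen] = {
                "tas": MonthlyClimateField(T, grid, "tas", "degC", scen, model_id),
                "tasmax": MonthlyClimateField(T + half, grid, "tasmax", "degC", scen, model_id),
                "tasmin": MonthlyClimateField(T - half, grid, "tasmin", "degC", scen, model_id),
                "pr": MonthlyClimateField(P, grid, "pr", "mm month-1", scen, model_id),
            }
    return PseudoGcmEnsemble(fields=fields, group_labels=labels, config=config, grid=grid)
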