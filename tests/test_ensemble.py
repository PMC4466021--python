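import numpy as np
import pandas as pd
import pytest
import xarray as xr

from lgmlayers import (
    EnsembleCube,
    GridSpec,
    agreement_mask,
    ensemble_qcd,
    ensemble_sd,
    region_summary,
    zonal_profile,
)
from lgmlayers.bioclim import BIO_NAMES


def make_cube(values_per_model, grid=None, variable="BIO1"):
    """Cube with one interesting variable; the rest are copies."""
    grid = grid or GridSpec(10.0, (-30, 30), (-20, 20))
    M = len(values_per_model)
    arr = np.zeros((19, M, *grid.shape))
    for m, v in enumerate(values_per_model):
        arr[:, m] = np.asarray(v, dtype=float)
    da = xr.DataArray(
        arr,
        dims=("variable", "model", "lat", "lon"),
        coords={
            "variable": list(BIO_NAMES),
            "model": [f"M{i}" for i in range(M)],
            "lat": grid.lat_centers,
            "lon": grid.lon_centers,
        },
    )
    return EnsembleCube(data=da, grid=grid)


def quartiles_oracle(values):
    """Type-7 quartiles by explicit order statistics."""
    x = np.sort(np.asarray(values, dtype=float))
    out = []
    for p in (0.25, 0.75):
        h = (len(x) - 1) * p
        lo = int(np.floor(h))
        hi = min(lo + 1, len(x) - 1)
        out.append(x[lo] + (h - lo) * (x[hi] - x[lo]))
    return out


class TestEnsembleSD:
    def test_identical_models_zero(self):
        cube = make_cube([np.full((4, 6), 3.0)] * 5)
        assert (np.asarray(ensemble_sd(cube, "BIO1")) == 0).all()

    def test_models_1_to_9_closed_form(self):
        cube = make_cube([np.full((4, 6), float(k)) for k in range(1, 10)])
        np.testing.assert_allclose(np.asarray(ensemble_sd(cube, "BIO1")), np.sqrt(7.5))

    def test_masked_model_uses_remaining(self):
        layers = [np.full((4, 6), float(k)) for k in range(1, 10)]
        layers[0][0, 0] = np.nan  # model 1 missing at a cell -> SD over 2..9
        cube = make_cube(layers)
        sd = np.asarray(ensemble_sd(cube, "BIO1"))
        assert sd[0, 0] == pytest.approx(np.std(np.arange(2, 10), ddof=1))
        assert sd[1, 1] == pytest.approx(np.sqrt(7.5))

    def test_fewer_than_two_models_masked(self):
        layers = [np.full((4, 6), 1.0), np.full((4, 6), 2.0)]
        layers[0][0, 0] = np.nan
        cube = make_cube(layers)
        assert np.isnan(np.asarray(ensemble_sd(cube, "BIO1"))[0, 0])

    def test_invariance_under_model_reordering(self, rng):
        layers = [rng.normal(size=(4, 6)) for _ in range(6)]
        a = np.asarray(ensemble_sd(make_cube(layers), "BIO1"))
        b = np.asarray(ensemble_sd(make_cube(layers[::-1]), "BIO1"))
        np.testing.assert_allclose(a, b)

    def test_scales_linearly(self, rng):
        layers = [rng.uniform(1, 5, size=(4, 6)) for _ in range(6)]
        a = np.asarray(ensemble_sd(make_cube(layers), "BIO12"))
        b = np.asarray(ensemble_sd(make_cube([3 * l for l in layers]), "BIO12"))
        np.testing.assert_allclose(b, 3 * a)


class TestEnsembleQCD:
    def test_printed_formula(self):
        # quartiles q1=1, q3=3 for values 0..4 (type 7) -> QCD = 0.5
        cube = make_cube([np.full((4, 6), float(k)) for k in range(5)], variable="BIO12")
        qcd = np.asarray(ensemble_qcd(cube, "BIO12"))
        q1, q3 = quartiles_oracle(range(5))
        assert (q1, q3) == (1.0, 3.0)
        np.testing.assert_allclose(qcd, 0.5)

    def test_identical_models_zero(self):
        cube = make_cube([np.full((4, 6), 7.0)] * 5)
        np.testing.assert_allclose(np.asarray(ensemble_qcd(cube, "BIO12")), 0.0)

    def test_nine_models_order_statistics_oracle(self, rng):
        """Random 9-model cells against explicit type-7 quartiles."""
        layers = [rng.uniform(10, 90, size=(4, 6)) for _ in range(9)]
        cube = make_cube(layers, variable="BIO12")
        qcd = np.asarray(ensemble_qcd(cube, "BIO12"))
        vals = np.stack(layers)
        for iy in range(4):
            for ix in range(6):
                q1, q3 = quartiles_oracle(vals[:, iy, ix])
                assert qcd[iy, ix] == pytest.approx((q3 - q1) / (q3 + q1))

    def test_temperature_shifted_to_kelvin(self):
        # sub-zero Celsius quartiles would break the plain formula
        cube = make_cube([np.full((4, 6), v) for v in (-12.0, -8.0, -4.0, 0.0, 4.0)])
        qcd = np.asarray(ensemble_qcd(cube, "BIO1"))
        q1, q3 = quartiles_oracle([-12, -8, -4, 0, 4])
        expected = ((q3 + 273.15) - (q1 + 273.15)) / ((q3 + 273.15) + (q1 + 273.15))
        np.testing.assert_allclose(qcd, expected)
        assert np.isfinite(qcd).all()

    def test_scale_invariance_on_absolute_scale(self, rng):
        layers = [rng.uniform(10, 50, size=(4, 6)) for _ in range(8)]
        a = np.asarray(ensemble_qcd(make_cube(layers, variable="BIO12"), "BIO12"))
        b = np.asarray(
            ensemble_qcd(make_cube([2.5 * l for l in layers], variable="BIO12"), "BIO12")
        )
        np.testing.assert_allclose(a, b)

    def test_too_few_models_masked(self):
        cube = make_cube([np.full((4, 6), float(k)) for k in range(3)], variable="BIO12")
        assert np.isnan(np.asarray(ensemble_qcd(cube, "BIO12"))).all()


class TestAgreementMask:
    def _qcd_maps(self, value, grid):
        coords = {"lat": grid.lat_centers, "lon": grid.lon_centers}
        return {
            v: xr.DataArray(np.full(grid.shape, value), dims=("lat", "lon"), coords=coords)
            for v in BIO_NAMES
        }

    def test_all_zero_agrees(self):
        grid = GridSpec(10.0, (-30, 30), (-20, 20))
        mask = agreement_mask(self._qcd_maps(0.0, grid))
        assert (np.asarray(mask) == 1).all()

    def test_single_bad_variable_breaks_agreement(self):
        grid = GridSpec(10.0, (-30, 30), (-20, 20))
        maps = self._qcd_maps(0.1, grid)
        maps["BIO15"] = maps["BIO15"] + 0.5  # 0.6 > threshold
        mask = agreement_mask(maps)
        assert (np.asarray(mask) == 0).all()

    def test_default_threshold_half_and_monotonicity(self):
        grid = GridSpec(10.0, (-30, 30), (-20, 20))
        maps = self._qcd_maps(0.4, grid)
        low = np.asarray(agreement_mask(maps, threshold=0.3))
        default = np.asarray(agreement_mask(maps))
        assert (low == 0).all() and (default == 1).all()
        # raising the threshold never removes an agreeing cell
        assert ((default == 1) >= (low == 1)).all()

    def test_masked_variable_undefined(self):
        grid = GridSpec(10.0, (-30, 30), (-20, 20))
        maps = self._qcd_maps(0.1, grid)
        arr = np.asarray(maps["BIO3"]).copy()
        arr[0, 0] = np.nan
        maps["BIO3"] = maps["BIO3"].copy(data=arr)
        mask = np.asarray(agreement_mask(maps))
        assert mask[0, 0] == 255
        assert mask[1, 1] == 1

    def test_missing_variable_rejected(self):
        grid = GridSpec(10.0, (-30, 30), (-20, 20))
        maps = self._qcd_maps(0.1, grid)
        del maps["BIO7"]
        with pytest.raises(ValueError):
            agreement_mask(maps)


class TestProfilesAndRegions:
    def test_constant_map_flat_profile(self):
        grid = GridSpec(5.0, (-30, 30), (-90, 90))
        da = xr.DataArray(
            np.full(grid.shape, 2.0), dims=("lat", "lon"),
            coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
        )
        prof = zonal_profile(da, band_width_deg=10.0)
        assert np.allclose(prof.dropna(), 2.0)
        assert prof.index.is_monotonic_increasing  # south -> north

    def test_abs_latitude_map_recovered(self):
        grid = GridSpec(5.0, (-30, 30), (-90, 90))
        lat2d = np.broadcast_to(grid.lat_centers[:, None], grid.shape)
        da = xr.DataArray(
            np.abs(lat2d), dims=("lat", "lon"),
            coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
        )
        prof = zonal_profile(da, band_width_deg=10.0)
        for center, val in prof.dropna().items():
            assert abs(val - abs(center)) <= 5.0  # within half a band

    def test_region_summary_matches_loop_oracle(self, rng):
        grid = GridSpec(10.0, (-30, 30), (-20, 20))
        values = rng.normal(size=grid.shape)
        labels = (np.indices(grid.shape).sum(axis=0) % 2).astype(int)  # checkerboard
        da = xr.DataArray(
            values, dims=("lat", "lon"),
            coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
        )
        table = region_summary(da, labels)
        for lab in (0, 1):
            vals = [values[iy, ix] for iy in range(grid.shape[0])
                    for ix in range(grid.shape[1]) if labels[iy, ix] == lab]
            assert table.loc[lab, "mean"] == pytest.approx(np.mean(vals))
            assert table.loc[lab, "sd"] == pytest.approx(np.std(vals, ddof=1))
            assert table.loc[lab, "n_cells"] == len(vals)

    def test_two_constant_regions(self):
        grid = GridSpec(10.0, (-30, 30), (-20, 20))
        values = np.full(grid.shape, 2.0)
        labels = np.zeros(grid.shape, dtype=int)
        labels[:, 3:] = 1
        values[:, 3:] = 5.0
        da = xr.DataArray(
            values, dims=("lat", "lon"),
            coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
        )
        table = region_summary(da, labels)
        assert table.loc[0, "mean"] == 2.0
        assert table.loc[1, "mean"] == 5.0

    def test_empty_region_reported(self):
        grid = GridSpec(10.0, (-30, 30), (-20, 20))
        values = np.full(grid.shape, np.nan)
        values[0, 0] = 1.0
        labels = np.zeros(grid.shape, dtype=int)
        labels[0, 0] = 1
        da = xr.DataArray(
            values, dims=("lat", "lon"),
            coords={"lat": grid.lat_centers, "lon": grid.lon_centers},
        )
        table = region_summary(da, labels)
        assert table.loc[0, "n_cells"] == 0
        assert pd.isna(table.loc[0, "mean"])
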