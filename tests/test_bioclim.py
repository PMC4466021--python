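import numpy as np
import pytest

from lgmlayers import BIO_NAMES, GridSpec, MonthlyClimateField, compute_bioclim, select_quarter
from lgmlayers.bioclim import QuarterIndex


def bioclim_oracle(tas, tasmax, tasmin, pr, ddof=1, bio15_offset=1.0):
    """Straight-from-definition oracle for one cell, explicit loops only."""
    def window(series, s):
        return [series[(s + k) % 12] for k in range(3)]

    pr_sums = [sum(window(pr, s)) for s in range(12)]
    tas_means = [sum(window(tas, s)) / 3 for s in range(12)]
    wettest = pr_sums.index(max(pr_sums))
    driest = pr_sums.index(min(pr_sums))
    warmest = tas_means.index(max(tas_means))
    coldest = tas_means.index(min(tas_means))

    out = {}
    out["BIO1"] = sum(tas) / 12
    out["BIO2"] = sum(tasmax[m] - tasmin[m] for m in range(12)) / 12
    out["BIO4"] = float(np.std(tas, ddof=ddof)) * 100
    out["BIO5"] = max(tasmax)
    out["BIO6"] = min(tasmin)
    out["BIO7"] = out["BIO5"] - out["BIO6"]
    out["BIO3"] = 100 * out["BIO2"] / out["BIO7"] if out["BIO7"] != 0 else np.nan
    out["BIO8"] = tas_means[wettest]
    out["BIO9"] = tas_means[driest]
    out["BIO10"] = tas_means[warmest]
    out["BIO11"] = tas_means[coldest]
    out["BIO12"] = sum(pr)
    out["BIO13"] = max(pr)
    out["BIO14"] = min(pr)
    out["BIO15"] = 100 * float(np.std(pr, ddof=ddof)) / (bio15_offset + sum(pr) / 12)
    out["BIO16"] = pr_sums[wettest]
    out["BIO17"] = pr_sums[driest]
    out["BIO18"] = pr_sums[warmest]
    out["BIO19"] = pr_sums[coldest]
    return out


def fields_from_arrays(tas, tasmax, tasmin, pr, grid):
    return (
        MonthlyClimateField(tas, grid, "tas", "degC"),
        MonthlyClimateField(tasmax, grid, "tasmax", "degC"),
        MonthlyClimateField(tasmin, grid, "tasmin", "degC"),
        MonthlyClimateField(pr, grid, "pr", "mm month-1"),
    )


def random_climate(rng, grid):
    tas = rng.uniform(-10, 25, size=(12, *grid.shape))
    half = rng.uniform(0.5, 8, size=(12, *grid.shape))
    pr = rng.uniform(0, 300, size=(12, *grid.shape))
    return fields_from_arrays(tas, tas + half, tas - half, pr, grid)


class TestSelectQuarter:
    def test_wettest_by_brute_force(self):
        pr = np.arange(1.0, 13.0)  # month index as value
        q = select_quarter(pr, "wettest")
        sums = [pr[s % 12] + pr[(s + 1) % 12] + pr[(s + 2) % 12] for s in range(12)]
        assert q.start_month == int(np.argmax(sums)) + 1 == 10
        assert q.months() == (10, 11, 12)

    def test_all_equal_ties_to_first_window(self):
        q = select_quarter(np.full(12, 5.0), "wettest")
        assert q.start_month == 1

    def test_wraparound_warmest_december(self):
        tas = np.full(12, 0.0)
        tas[[11, 0, 1]] = 20.0  # Dec-Jan-Feb peak
        q = select_quarter(tas, "warmest")
        assert q.start_month == 12
        assert q.months() == (12, 1, 2)

    @pytest.mark.parametrize("criterion", ["wettest", "driest", "warmest", "coldest"])
    def test_matches_exhaustive_window_oracle(self, criterion, rng):
        for _ in range(25):
            x = rng.uniform(0, 100, size=12)
            q = select_quarter(x, criterion)
            stats = [
                (x[s % 12] + x[(s + 1) % 12] + x[(s + 2) % 12])
                / (1 if criterion in ("wettest", "driest") else 3)
                for s in range(12)
            ]
            best = max(stats) if criterion in ("wettest", "warmest") else min(stats)
            assert stats[q.start_month - 1] == pytest.approx(best)
            # tie rule: no earlier window attains the extremum
            assert all(
                not np.isclose(stats[s], best) for s in range(q.start_month - 1)
            ) or stats.index(best) == q.start_month - 1

    def test_non_finite_rejected(self):
        x = np.full(12, 1.0)
        x[4] = np.nan
        with pytest.raises(ValueError):
            select_quarter(x, "wettest")


class TestComputeBioclim:
    GRID = GridSpec(10.0, (-30, 30), (-20, 20))

    def test_constant_climate_closed_forms(self):
        g = self.GRID
        shape = (12, *g.shape)
        stack = compute_bioclim(
            *fields_from_arrays(
                np.full(shape, 10.0), np.full(shape, 15.0),
                np.full(shape, 5.0), np.full(shape, 100.0), g,
            )
        )
        expected = {
            "BIO1": 10, "BIO2": 10, "BIO3": 100, "BIO4": 0, "BIO5": 15, "BIO6": 5,
            "BIO7": 10, "BIO8": 10, "BIO9": 10, "BIO10": 10, "BIO11": 10,
            "BIO12": 1200, "BIO13": 100, "BIO14": 100, "BIO15": 0,
            "BIO16": 300, "BIO17": 300, "BIO18": 300, "BIO19": 300,
        }
        for name, val in expected.items():
            np.testing.assert_allclose(stack[name], val, err_msg=name)

    def test_bio1_comes_from_tas_not_midpoint(self):
        g = self.GRID
        shape = (12, *g.shape)
        stack = compute_bioclim(
            *fields_from_arrays(
                np.full(shape, 20.0), np.full(shape, 26.0),
                np.full(shape, 10.0), np.full(shape, 50.0), g,
            )
        )
        # midpoint of tasmax/tasmin is 18; BIO1 must follow tas
        np.testing.assert_allclose(stack["BIO1"], 20.0)

    def test_random_cells_match_definition_oracle(self, rng):
        grid = GridSpec(6.0, (-90, 90), (-48, 48))  # 16 x 30 = 480 cells
        tas, tasmax, tasmin, pr = random_climate(rng, grid)
        stack = compute_bioclim(tas, tasmax, tasmin, pr)
        ny, nx = grid.shape
        cells = [(rng.integers(ny), rng.integers(nx)) for _ in range(60)]
        for iy, ix in cells:
            oracle = bioclim_oracle(
                tas.data[:, iy, ix].tolist(), tasmax.data[:, iy, ix].tolist(),
                tasmin.data[:, iy, ix].tolist(), pr.data[:, iy, ix].tolist(),
            )
            for name in BIO_NAMES:
                assert stack[name][iy, ix] == pytest.approx(oracle[name], rel=1e-10), name

    def test_stack_invariants_hold(self, rng):
        grid = GridSpec(10.0, (-180, 180), (-90, 90))
        tas, tasmax, tasmin, pr = random_climate(rng, grid)
        s = compute_bioclim(tas, tasmax, tasmin, pr)
        assert (s["BIO5"] >= s["BIO6"]).all()
        np.testing.assert_allclose(s["BIO7"], s["BIO5"] - s["BIO6"])
        assert (s["BIO13"] >= s["BIO14"]).all()
        np.testing.assert_allclose(s["BIO12"], pr.data.sum(axis=0))
        assert (s["BIO10"] >= s["BIO11"]).all()
        assert (s["BIO16"] >= s["BIO17"]).all()
        for name in ("BIO12", "BIO13", "BIO14", "BIO16", "BIO17", "BIO18", "BIO19"):
            assert (s[name] >= 0).all()

    def test_month_rotation_invariance(self, rng):
        """Rotating all four inputs by the same offset leaves every layer
        unchanged (quarters wrap)."""
        grid = GridSpec(15.0, (-30, 30), (-30, 30))
        tas, tasmax, tasmin, pr = random_climate(rng, grid)
        a = compute_bioclim(tas, tasmax, tasmin, pr)
        k = 5
        rolled = [
            f.with_data(np.roll(f.data, k, axis=0)) for f in (tas, tasmax, tasmin, pr)
        ]
        b = compute_bioclim(*rolled)
        np.testing.assert_allclose(a.data, b.data, rtol=1e-12)

    def test_masked_cell_propagates(self, rng):
        grid = self.GRID
        tas, tasmax, tasmin, pr = random_climate(rng, grid)
        tas.data[3, 1, 1] = np.nan
        stack = compute_bioclim(tas, tasmax, tasmin, pr)
        assert np.isnan(stack.data[:, 1, 1]).all()
        assert np.isfinite(stack.data[:, 0, 0]).all()

    def test_misaligned_grids_rejected(self, rng):
        grid = self.GRID
        other = GridSpec(5.0, (-30, 30), (-20, 20))
        tas, tasmax, tasmin, pr = random_climate(rng, grid)
        pr_other = MonthlyClimateField(
            np.zeros((12, *other.shape)), other, "pr", "mm month-1"
        )
        with pytest.raises(ValueError):
            compute_bioclim(tas, tasmax, tasmin, pr_other)

    def test_netcdf_roundtrip(self, tmp_path, rng):
        grid = self.GRID
        stack = compute_bioclim(*random_climate(rng, grid))
        path = tmp_path / "bio.nc"
        stack.to_netcdf(path)
        import xarray as xr

        from lgmlayers.bioclim import BioclimStack

        with xr.open_dataset(path, engine="scipy") as ds:
            back = BioclimStack.from_dataset(ds.load())
        np.testing.assert_allclose(back.data, stack.data, rtol=1e-6)


class TestQuarterIndex:
    def test_wraparound_months(self):
        assert QuarterIndex(11, "coldest").months() == (11, 12, 1)
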