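"""Horizon averaging, delta bias correction, bioclim indices, aggregation."""

import numpy as np
import pytest

from amocrange import (
    ClimateCube,
    GridSpec,
    PeriodClimatology,
    aggregate_grid,
    compute_bioclim,
    delta_bias_correct,
    horizon_mean,
)
from amocrange.climate_prep import BIOCLIM_VARS
from amocrange.errors import AlignmentError, ParameterError

GRID = GridSpec(4, 5, 1.0)


def make_cube(years, tmean=10.0, spread=5.0, prec=100.0, trend=0.0):
    """Cube with spatially constant fields, optional linear trend in tmean."""
    years = np.asarray(years)
    shape = (len(years), 12, GRID.n_rows, GRID.n_cols)
    tm = np.full(shape, tmean) + trend * (years - years[0])[:, None, None, None]
    pr = np.broadcast_to(np.asarray(prec, dtype=float), (12,))[None, :, None, None]
    return ClimateCube(
        grid=GRID,
        years=years,
        data={
            "tmean": tm,
            "tmax": tm + spread,
            "tmin": tm - spread,
            "prec": np.broadcast_to(pr, shape).copy(),
        },
    )


def clim(tmean, tmax, tmin, prec):
    """12-month climatology from per-month arrays or scalars."""

    def month_field(values):
        v = np.broadcast_to(np.asarray(values, dtype=float), (12,))
        return np.tile(v[:, None, None], (1, GRID.n_rows, GRID.n_cols))

    return PeriodClimatology(
        grid=GRID,
        data={
            "tmean": month_field(tmean),
            "tmax": month_field(tmax),
            "tmin": month_field(tmin),
            "prec": month_field(prec),
        },
        center_year=1985,
        width=30,
    )


class TestHorizonMean:
    def test_constant_cube_returns_constant(self):
        cube = make_cube(range(2000, 2040))
        out = horizon_mean(cube, center_year=2020, width=30)
        assert np.allclose(out.data["tmean"], 10.0)
        assert out.data["tmean"].shape == (12, 4, 5)

    def test_width_one_returns_single_year(self):
        cube = make_cube(range(2000, 2010), trend=1.0)
        out = horizon_mean(cube, center_year=2005, width=1)
        assert np.allclose(out.data["tmean"], 10.0 + 5.0)

    def test_linear_trend_gives_window_midpoint(self):
        # arithmetic mean of an arithmetic progression = value at midpoint
        cube = make_cube(range(2000, 2060), trend=0.2)
        out = horizon_mean(cube, center_year=2030, width=30)
        years = np.arange(2015, 2045)
        expected = 10.0 + 0.2 * (years.mean() - 2000)
        assert np.allclose(out.data["tmean"], expected)

    def test_window_outside_cube_raises(self):
        cube = make_cube(range(2000, 2020))
        with pytest.raises(AlignmentError):
            horizon_mean(cube, center_year=2018, width=30)


class TestDeltaBiasCorrect:
    def test_zero_bias_leaves_target_unchanged(self):
        base = clim(10, 15, 5, 100)
        target = clim(14, 19, 9, 80)
        out = delta_bias_correct(base, base, target)
        for var in ("tmean", "tmax", "tmin", "prec"):
            assert np.array_equal(out.data[var], target.data[var])

    def test_constant_warm_bias_subtracted(self):
        obs = clim(10, 15, 5, 100)
        model = clim(12, 17, 7, 100)  # uniform +2 degC bias
        target = clim(20, 25, 15, 100)
        out = delta_bias_correct(model, obs, target)
        assert np.allclose(out.data["tmean"], 18.0)
        assert np.allclose(out.data["tmax"], 23.0)

    def test_correcting_model_baseline_recovers_observations(self):
        obs = clim([5 + m for m in range(12)], 20, -5, [50 + 5 * m for m in range(12)])
        model = clim([7 + m for m in range(12)], 23, -3, [80 + 5 * m for m in range(12)])
        out = delta_bias_correct(model, obs, model)
        for var in ("tmean", "tmax", "tmin", "prec"):
            np.testing.assert_allclose(out.data[var], obs.data[var], atol=1e-12)

    def test_precipitation_clamped_at_zero(self):
        obs = clim(10, 15, 5, 100)
        model = clim(10, 15, 5, 125)  # +25 mm wet bias
        target = clim(10, 15, 5, 10)
        out = delta_bias_correct(model, obs, target)
        assert np.all(out.data["prec"] == 0.0)

    def test_grid_mismatch_raises(self):
        other = PeriodClimatology(
            grid=GridSpec(2, 2, 1.0),
            data={v: np.zeros((12, 2, 2)) for v in ("tmean", "tmax", "tmin", "prec")},
            center_year=1985,
            width=30,
        )
        base = clim(10, 15, 5, 100)
        with pytest.raises(AlignmentError):
            delta_bias_correct(base, base, other)


class TestComputeBioclim:
    def test_constant_months(self):
        out = compute_bioclim(clim(10, 15, 5, 100))
        assert np.allclose(out.data["bio1"], 10)
        assert np.allclose(out.data["bio5"], 15)
        assert np.allclose(out.data["bio6"], 5)
        assert np.allclose(out.data["bio12"], 1200)
        assert np.allclose(out.data["bio15"], 0)

    def test_bio5_is_max_of_monthly_tmax(self):
        out = compute_bioclim(clim(0, list(range(1, 13)), -1, 100))
        assert np.allclose(out.data["bio5"], 12)

    def test_alternating_precipitation_seasonality(self):
        # oracle: direct evaluation of 100 * sd(m+1, ddof=1) / mean(m+1)
        prec = [50, 150] * 6
        out = compute_bioclim(clim(10, 15, 5, prec))
        m1 = np.asarray(prec, dtype=float) + 1.0
        expected15 = 100.0 * m1.std(ddof=1) / m1.mean()
        assert np.allclose(out.data["bio12"], 1200)
        np.testing.assert_allclose(out.data["bio15"], expected15, rtol=1e-12)

    def test_temperature_shift_equivariance(self):
        """bio1/5/6 commute with a constant temperature offset."""
        months = np.linspace(-5, 20, 12)
        a = compute_bioclim(clim(months, months + 6, months - 6, 100))
        b = compute_bioclim(clim(months + 3, months + 9, months - 3, 100))
        for var in ("bio1", "bio5", "bio6"):
            np.testing.assert_allclose(b.data[var], a.data[var] + 3, atol=1e-12)
        np.testing.assert_allclose(b.data["bio15"], a.data["bio15"])

    def test_bio15_scale_invariance_for_large_precip(self):
        prec = np.linspace(100, 400, 12)
        a = compute_bioclim(clim(10, 15, 5, prec))
        b = compute_bioclim(clim(10, 15, 5, 10 * prec))
        np.testing.assert_allclose(a.data["bio15"], b.data["bio15"], rtol=2e-2)


class TestAggregateGrid:
    def _stack(self, arr):
        from amocrange import BioclimStack

        grid = GridSpec(arr.shape[0], arr.shape[1], 1.0)
        return BioclimStack(grid=grid, data={v: arr.astype(float) for v in BIOCLIM_VARS})

    def test_block_mean(self):
        arr = np.arange(1, 10).reshape(3, 3)
        out = aggregate_grid(self._stack(arr), 3)
        assert out.data["bio1"].shape == (1, 1)
        assert out.data["bio1"][0, 0] == 5.0

    def test_masked_cells_excluded(self):
        arr = np.full((3, 3), np.nan)
        arr[1, 1] = 7.0
        out = aggregate_grid(self._stack(arr), 3)
        assert out.data["bio1"][0, 0] == 7.0

    def test_fully_masked_block_stays_masked(self):
        arr = np.full((3, 3), np.nan)
        out = aggregate_grid(self._stack(arr), 3)
        assert np.isnan(out.data["bio1"][0, 0])

    def test_factor_one_is_identity(self):
        arr = np.arange(9.0).reshape(3, 3)
        out = aggregate_grid(self._stack(arr), 1)
        np.testing.assert_array_equal(out.data["bio1"], arr)

    def test_grand_mean_conserved_when_unmasked(self, rng):
        arr = rng.normal(size=(6, 9))
        out = aggregate_grid(self._stack(arr), 3)
        np.testing.assert_allclose(out.data["bio1"].mean(), arr.mean())

    def test_bad_factor_raises(self):
        with pytest.raises(ParameterError):
            aggregate_grid(self._stack(np.zeros((3, 3))), 0)

    def test_indivisible_grid_raises(self):
        with pytest.raises(ParameterError):
            aggregate_grid(self._stack(np.zeros((4, 4))), 3)
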