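import numpy as np
import pytest

from nvcoupling.preprocess import (
    MotionTrace,
    NuisanceSet,
    bandpass,
    drop_initial_volumes,
    friston24,
    regress_nuisance,
    smooth_gaussian,
)
from nvcoupling.volumes import BoldSeries, Grid, MaskMap, ScalarMap


def make_series(rng, shape=(3, 3, 3), T=200, tr=2.0):
    return BoldSeries(Grid.isotropic(shape, 3.0), rng.standard_normal(shape + (T,)), tr)


class TestDropInitialVolumes:
    def test_210_minus_10_is_200(self, rng):
        series = make_series(rng, T=210)
        out = drop_initial_volumes(series, 10)
        assert out.n_timepoints == 200
        assert np.array_equal(out.values, series.values[..., 10:])

    def test_zero_drop_is_identity(self, rng):
        series = make_series(rng, T=20)
        assert np.array_equal(drop_initial_volumes(series, 0).values, series.values)

    def test_dropping_everything_errors(self, rng):
        with pytest.raises(ValueError):
            drop_initial_volumes(make_series(rng, T=5), 5)


class TestFriston24:
    def test_zero_motion_gives_zero_columns(self):
        out = friston24(MotionTrace(np.zeros((50, 6))))
        assert out.regressors.shape == (50, 24)
        assert np.all(out.regressors == 0)

    def test_lag_and_square_definition(self):
        t = np.arange(1.0, 7.0)
        params = np.zeros((6, 6))
        params[:, 0] = t
        out = friston24(MotionTrace(params))
        lag = out.regressors[:, 6]
        assert lag[0] == 0 and np.array_equal(lag[1:], t[:-1])
        assert np.array_equal(out.regressors[:, 12], t**2)
        assert np.array_equal(out.regressors[:, 18], lag**2)

    def test_matches_naive_loop_construction(self, rng):
        p = rng.standard_normal((30, 6))
        out = friston24(MotionTrace(p)).regressors
        expected = np.zeros((30, 24))
        for t in range(30):
            for j in range(6):
                expected[t, j] = p[t, j]
                expected[t, 6 + j] = p[t - 1, j] if t > 0 else 0.0
                expected[t, 12 + j] = p[t, j] ** 2
                expected[t, 18 + j] = (p[t - 1, j] if t > 0 else 0.0) ** 2
        assert np.array_equal(out, expected)

    def test_too_short_trace_errors(self):
        with pytest.raises(ValueError):
            friston24(MotionTrace(np.zeros((1, 6))))


class TestRegressNuisance:
    def test_self_regression_annihilates(self, rng):
        series = make_series(rng, T=60)
        mask = MaskMap(series.grid, np.ones(series.grid.shape, bool))
        voxel = series.values[1, 1, 1]
        out = regress_nuisance(
            series, NuisanceSet(voxel[:, None], ["self"]), mask, include_trend=False
        )
        assert np.abs(out.values[1, 1, 1]).max() < 1e-8

    def test_orthogonal_nuisance_leaves_demeaned_input(self, rng):
        T = 64
        series = make_series(rng, T=T)
        mask = MaskMap(series.grid, np.ones(series.grid.shape, bool))
        # projection oracle: orthogonalize a regressor against every voxel series
        reg = rng.standard_normal(T)
        flat = series.values.reshape(-1, T)
        basis = np.linalg.svd(np.vstack([flat, np.ones(T)]), full_matrices=False)[2]
        reg = reg - basis.T @ (basis @ reg)
        out = regress_nuisance(
            series, NuisanceSet(reg[:, None], ["orth"]), mask, include_trend=False
        )
        demeaned = series.values - series.values.mean(axis=-1, keepdims=True)
        assert np.allclose(out.values, demeaned, atol=1e-8)

    def test_residuals_orthogonal_to_design(self, rng):
        series = make_series(rng, T=80)
        mask = MaskMap(series.grid, np.ones(series.grid.shape, bool))
        nuis = NuisanceSet(rng.standard_normal((80, 4)), list("abcd"))
        out = regress_nuisance(series, nuis, mask)
        resid = out.values.reshape(-1, 80)
        for j in range(4):
            r = nuis.regressors[:, j]
            corr = resid @ r / (np.linalg.norm(resid, axis=1) * np.linalg.norm(r))
            assert np.abs(corr).max() < 1e-8

    def test_out_of_mask_untouched(self, rng):
        series = make_series(rng, T=40)
        inside = np.zeros(series.grid.shape, bool)
        inside[0, 0, 0] = True
        out = regress_nuisance(
            series, NuisanceSet(rng.standard_normal((40, 2)), ["a", "b"]),
            MaskMap(series.grid, inside),
        )
        assert np.array_equal(out.values[1:], series.values[1:])

    def test_rank_deficiency_names_columns(self, rng):
        series = make_series(rng, T=40)
        mask = MaskMap(series.grid, np.ones(series.grid.shape, bool))
        x = rng.standard_normal(40)
        nuis = NuisanceSet(np.column_stack([x, 2 * x]), ["wm", "wm_scaled"])
        with pytest.raises(ValueError, match="wm"):
            regress_nuisance(series, nuis, mask)

    def test_exact_duplicates_dropped_silently(self, rng):
        series = make_series(rng, T=40)
        mask = MaskMap(series.grid, np.ones(series.grid.shape, bool))
        x = rng.standard_normal(40)
        nuis = NuisanceSet(np.column_stack([x, x]), ["a", "a_copy"])
        regress_nuisance(series, nuis, mask)  # no error


class TestBandpass:
    def make_tone(self, freq, T=200, tr=2.0):
        t = np.arange(T) * tr
        vals = np.zeros((1, 1, 1, T))
        vals[0, 0, 0] = np.sin(2 * np.pi * freq * t)
        return BoldSeries(Grid.isotropic((1, 1, 1), 3.0), vals, tr)

    def test_in_band_tone_passes(self):
        out = bandpass(self.make_tone(0.05))
        assert np.abs(out.values).max() >= 0.95

    def test_out_of_band_tone_rejected(self):
        out = bandpass(self.make_tone(0.2))
        assert np.abs(out.values).max() <= 0.05

    def test_constant_series_zeroed(self):
        series = BoldSeries(Grid.isotropic((1, 1, 1), 3.0), np.full((1, 1, 1, 100), 7.0), 2.0)
        assert np.abs(bandpass(series).values).max() < 1e-10

    def test_band_outside_nyquist_errors(self, rng):
        with pytest.raises(ValueError):
            bandpass(make_series(rng, T=50), 0.01, 0.3)  # Nyquist = 0.25 Hz


class TestSmoothGaussian:
    def test_zero_fwhm_is_identity(self, grid5, full_mask5, rng):
        m = ScalarMap(grid5, rng.standard_normal(grid5.shape))
        out = smooth_gaussian(m, 0.0, full_mask5)
        assert np.array_equal(out.values, m.values)

    def test_constant_preserved_in_mask(self, grid5, rng):
        inside = rng.random(grid5.shape) > 0.4
        inside[2, 2, 2] = True
        mask = MaskMap(grid5, inside)
        m = ScalarMap(grid5, np.full(grid5.shape, 3.5))
        out = smooth_gaussian(m, 6.0, mask)
        assert np.allclose(out.values[inside], 3.5, atol=1e-10)
        assert np.all(np.isnan(out.values[~inside]))

    def test_impulse_matches_analytic_kernel(self):
        # closed-form oracle: normalized samples of the separable Gaussian
        grid = Grid.isotropic((21, 21, 21), 3.0)
        vals = np.zeros(grid.shape)
        vals[10, 10, 10] = 1.0
        fwhm = 6.0
        out = smooth_gaussian(ScalarMap(grid, vals), fwhm)
        sigma = fwhm / (2 * np.sqrt(2 * np.log(2))) / 3.0
        radius = int(4.0 * sigma + 0.5)
        offsets = np.arange(-radius, radius + 1)
        w = np.exp(-0.5 * (offsets / sigma) ** 2)
        w /= w.sum()
        expected = np.zeros(grid.shape)
        for i, wi in zip(offsets, w):
            for j, wj in zip(offsets, w):
                for k, wk in zip(offsets, w):
                    expected[10 + i, 10 + j, 10 + k] = wi * wj * wk
        assert np.allclose(out.values, expected, atol=1e-6)

    def test_no_bleed_across_mask(self, grid5, rng):
        inside = np.zeros(grid5.shape, bool)
        inside[:2] = True
        vals = np.zeros(grid5.shape)
        vals[4, 4, 4] = 100.0  # outside the mask
        out = smooth_gaussian(ScalarMap(grid5, vals), 6.0, MaskMap(grid5, inside))
        assert np.allclose(out.values[inside], 0.0)


class TestMotionTrace:
    def test_screening_bounds(self):
        ok = MotionTrace(np.full((10, 6), 0.001))
        assert ok.passes_screening()
        bad = np.zeros((10, 6))
        bad[5, 2] = 2.5  # 2.5 mm translation
        assert not MotionTrace(bad).passes_screening()

    def test_file_roundtrip(self, tmp_path, rng):
        trace = MotionTrace(rng.standard_normal((20, 6)) * 0.01)
        trace.to_file(tmp_path / "mot.txt")
        back = MotionTrace.from_file(tmp_path / "mot.txt")
        assert np.allclose(back.params, trace.params, atol=1e-8)


def test_voxelwise_permutation_equivariance(rng):
    """Filtering and regression are per-voxel: permuting voxels permutes outputs."""
    series = make_series(rng, shape=(2, 2, 2), T=60)
    mask = MaskMap(series.grid, np.ones(series.grid.shape, bool))
    nuis = NuisanceSet(rng.standard_normal((60, 3)), list("abc"))
    out = bandpass(regress_nuisance(series, nuis, mask))
    flipped = BoldSeries(series.grid, series.values[::-1].copy(), series.tr_seconds)
    out_flipped = bandpass(regress_nuisance(flipped, nuis, mask))
    assert np.allclose(out.values[::-1], out_flipped.values, atol=1e-12)
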