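import numpy as np
import pytest

from nvcoupling.metrics import DcParams, FalffParams, degree_centrality, falff, zscore_map
from nvcoupling.preprocess import band_fraction
from nvcoupling.volumes import BoldSeries, Grid, MaskMap, ScalarMap


def brute_force_dc(series, mask, params):
    """O(M^2) pairwise-correlation oracle for degree centrality."""
    X = series.values[mask.inside]
    M = X.shape[0]
    out = np.zeros(M)
    for i in range(M):
        for j in range(M):
            if i == j:
                continue
            r = np.corrcoef(X[i], X[j])[0, 1]
            if r >= params.r_threshold:
                out[i] += 1.0 if params.mode == "binary_count" else r
    if params.normalize:
        out /= M - 1
    full = np.full(series.grid.shape, np.nan)
    full[mask.inside] = out
    return full


def make_series(values, tr=2.0):
    values = np.asarray(values, float)
    return BoldSeries(Grid.isotropic(values.shape[:3], 3.0), values, tr)


class TestDegreeCentrality:
    def test_identical_series_fully_connected(self, rng):
        t = rng.standard_normal(30)
        vals = np.zeros((3, 1, 1, 30))
        vals[:, 0, 0] = t
        series = make_series(vals)
        mask = MaskMap(series.grid, np.ones((3, 1, 1), bool))
        out = degree_centrality(series, mask)
        assert np.allclose(out.values[mask.inside], 1.0)

    def test_orthogonal_sinusoids_have_no_edges(self):
        t = np.arange(60)
        vals = np.zeros((3, 1, 1, 60))
        for k in range(3):
            vals[k, 0, 0] = np.sin(2 * np.pi * (k + 1) * t / 60)
        series = make_series(vals)
        mask = MaskMap(series.grid, np.ones((3, 1, 1), bool))
        out = degree_centrality(series, mask)
        assert np.all(out.values[mask.inside] == 0.0)

    @pytest.mark.parametrize("mode", ["binary_count", "weighted_sum"])
    @pytest.mark.parametrize("threshold", [0.15, 0.2, 0.25])
    def test_matches_brute_force_oracle(self, rng, mode, threshold):
        series = make_series(rng.standard_normal((4, 4, 4, 60)))
        mask = MaskMap(series.grid, rng.random((4, 4, 4)) > 0.3)
        params = DcParams(r_threshold=threshold, mode=mode)
        out = degree_centrality(series, mask, params)
        expected = brute_force_dc(series, mask, params)
        assert np.allclose(out.values[mask.inside], expected[mask.inside], atol=1e-10)

    def test_blocked_computation_block_size_invariant(self, rng):
        series = make_series(rng.standard_normal((4, 4, 4, 40)))
        mask = MaskMap(series.grid, np.ones((4, 4, 4), bool))
        ref = degree_centrality(series, mask, block_size=64)
        for bs in (1, 3, 17, 1000):
            out = degree_centrality(series, mask, block_size=bs)
            assert np.allclose(out.values[mask.inside], ref.values[mask.inside],
                               atol=1e-10)

    def test_affine_rescaling_invariance(self, rng):
        vals = rng.standard_normal((3, 3, 1, 50))
        series = make_series(vals)
        mask = MaskMap(series.grid, np.ones((3, 3, 1), bool))
        ref = degree_centrality(series, mask)
        vals2 = vals.copy()
        vals2[1, 2, 0] = 3.7 * vals2[1, 2, 0] + 11.0
        out = degree_centrality(make_series(vals2), mask)
        assert np.allclose(out.values[mask.inside], ref.values[mask.inside], atol=1e-10)

    def test_constant_voxel_reported_with_indices(self, rng):
        vals = rng.standard_normal((2, 2, 1, 30))
        vals[1, 0, 0] = 5.0
        series = make_series(vals)
        mask = MaskMap(series.grid, np.ones((2, 2, 1), bool))
        with pytest.raises(ValueError, match=r"\(1, 0, 0\)"):
            degree_centrality(series, mask)

    def test_out_of_mask_missing(self, rng):
        series = make_series(rng.standard_normal((3, 3, 3, 40)))
        inside = np.zeros((3, 3, 3), bool)
        inside[0] = True
        out = degree_centrality(series, MaskMap(series.grid, inside))
        assert np.all(np.isnan(out.values[~inside]))
        assert np.all(np.isfinite(out.values[inside]))


class TestFalff:
    def tone(self, freq, T=200, tr=2.0):
        t = np.arange(T) * tr
        vals = np.zeros((1, 1, 1, T))
        vals[0, 0, 0] = np.sin(2 * np.pi * freq * t)
        return make_series(vals, tr)

    def test_in_band_tone_near_one(self):
        series = self.tone(0.05)
        mask = MaskMap(series.grid, np.ones((1, 1, 1), bool))
        assert falff(series, mask).values[0, 0, 0] >= 0.95

    def test_out_of_band_tone_near_zero(self):
        series = self.tone(0.2)
        mask = MaskMap(series.grid, np.ones((1, 1, 1), bool))
        assert falff(series, mask).values[0, 0, 0] <= 0.05

    def test_white_noise_mean_matches_flat_spectrum(self, rng):
        # 500 independent white-noise voxels; flat amplitude spectrum in
        # expectation, so mean fALFF ~ n_in_band / n_positive bins
        T = 200
        vals = rng.standard_normal((500, 1, 1, T))
        series = make_series(vals)
        mask = MaskMap(series.grid, np.ones((500, 1, 1), bool))
        out = falff(series, mask).values[mask.inside]
        n_band, n_pos = band_fraction(T, 2.0)
        expect = n_band / n_pos
        mc_se = out.std() / np.sqrt(out.size)
        assert abs(out.mean() - expect) < 3 * mc_se + 1e-3

    def test_bounded_unit_interval(self, rng):
        series = make_series(rng.standard_normal((4, 4, 4, 64)))
        mask = MaskMap(series.grid, np.ones((4, 4, 4), bool))
        vals = falff(series, mask).values[mask.inside]
        assert np.all((vals >= 0) & (vals <= 1))

    def test_constant_series_errors(self):
        series = make_series(np.ones((1, 1, 1, 50)))
        mask = MaskMap(series.grid, np.ones((1, 1, 1), bool))
        with pytest.raises(ValueError):
            falff(series, mask)


class TestZscoreMap:
    def test_three_values_definitional(self):
        grid = Grid.isotropic((3, 1, 1), 3.0)
        m = ScalarMap(grid, np.array([1.0, 2.0, 3.0]).reshape(3, 1, 1))
        out = zscore_map(m, MaskMap(grid, np.ones((3, 1, 1), bool)))
        assert np.allclose(out.values.ravel(), [-1, 0, 1])

    def test_constant_map_errors(self, grid5, full_mask5):
        with pytest.raises(ValueError):
            zscore_map(ScalarMap(grid5, np.full(grid5.shape, 2.0)), full_mask5)

    def test_normalization_identity(self, grid5, full_mask5, rng):
        out = zscore_map(ScalarMap(grid5, rng.standard_normal(grid5.shape)), full_mask5)
        vals = out.values[full_mask5.inside]
        assert abs(vals.mean()) < 1e-10
        assert abs(vals.std(ddof=1) - 1) < 1e-10

    def test_missing_stays_missing(self, grid5, full_mask5, rng):
        vals = rng.standard_normal(grid5.shape)
        missing = np.zeros(grid5.shape, bool)
        missing[1, 1, 1] = True
        out = zscore_map(ScalarMap(grid5, vals, missing), full_mask5)
        assert np.isnan(out.values[1, 1, 1])
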