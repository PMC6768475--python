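import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import nestdensity as nd
from nestdensity.evaluation import BinTable, bin_index


def _bins(area, counts):
    area = np.asarray(area, dtype=float)
    K = len(area)
    t = BinTable(edges=np.linspace(0, 1, K + 1), area=area,
                 counts=np.asarray(counts))
    return nd.area_adjusted_frequency(t)


class TestBinEdges:
    def test_upper_bin_convention(self):
        edges = np.linspace(0, 1, 11)
        vals = np.array([0.0, 0.1, 0.55, 0.999, 1.0])
        assert bin_index(vals, edges).tolist() == [0, 1, 5, 9, 9]

    def test_constant_surface_single_bin(self, fitted):
        surf = fitted["surface"]
        const = nd.RNDSurface(surf.grid, np.full(surf.grid.shape, 0.55),
                              np.full(surf.grid.shape, 1.0), "logistic")
        table = nd.bin_rnd_surface(const)
        assert table.p_A[5] == pytest.approx(1.0)

    def test_uniform_random_surface_equal_bins(self, small_grid):
        rng = np.random.default_rng(0)
        vals = rng.uniform(0, 1, small_grid.shape)
        surf = nd.RNDSurface(small_grid, vals, vals, "logistic")
        table = nd.bin_rnd_surface(surf)
        np.testing.assert_allclose(table.p_A, 0.1, atol=0.02)

    def test_k_below_two_rejected(self, fitted):
        with pytest.raises(ValueError):
            nd.bin_rnd_surface(fitted["surface"], K=1)


class TestAAF:
    def test_direct_arithmetic(self):
        t = _bins([80, 20], [2, 8])
        np.testing.assert_allclose(t.aaf, [0.25, 4.0])

    def test_identity_sum_pA_aaf(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(1, 100, 10)
        n = rng.integers(0, 50, 10)
        n[0] = 1  # ensure N > 0
        t = _bins(a, n)
        assert float(np.nansum(t.p_A * t.aaf)) == pytest.approx(1.0, abs=1e-12)

    def test_uniform_nests_give_unit_aaf(self, small_grid):
        rng = np.random.default_rng(2)
        vals = rng.uniform(0, 1, small_grid.shape)
        surf = nd.RNDSurface(small_grid, vals, vals, "logistic")
        table = nd.bin_rnd_surface(surf)
        b = small_grid.bounds
        xy = np.column_stack([rng.uniform(b[0], b[2], 10000),
                              rng.uniform(b[1] + 1e-6, b[3], 10000)])
        table = nd.count_nests_in_bins(table, surf, xy)
        table = nd.area_adjusted_frequency(table)
        assert np.all(np.abs(table.aaf - 1.0) < 0.1)

    def test_empty_bins_undefined(self):
        t = _bins([50, 0, 50], [5, 0, 5])
        assert np.isnan(t.aaf[1])

    def test_impossible_geometry_rejected(self):
        with pytest.raises(ValueError, match="zero-area"):
            _bins([50, 0], [5, 5])


class TestPredictedCounts:
    def test_direct_eq_arithmetic(self):
        pred = nd.predicted_bin_counts(100, np.array([0.8, 0.2]),
                                       np.array([0.25, 4.0]))
        np.testing.assert_allclose(pred["N_p"], [20.0, 80.0])
        assert pred["N_p"].sum() == pytest.approx(100.0)

    def test_unit_aaf_gives_area_proportional_counts(self):
        p_A = np.array([0.5, 0.3, 0.2])
        pred = nd.predicted_bin_counts(60, p_A, np.ones(3))
        np.testing.assert_allclose(pred["N_p"], 60 * p_A)

    @given(st.integers(0, 10_000), st.integers(2, 12), st.integers(0, 2**31 - 1))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_conservation_property(self, N_t, K, seed):
        """Sum of predicted counts equals the test total whenever p_A and
        AAF come from one binning (conservation via sum p_A * AAF = 1)."""
        rng = np.random.default_rng(seed)
        a = rng.uniform(0.1, 10, K)
        n = rng.integers(0, 100, K)
        if n.sum() == 0:
            n[0] = 1
        t = _bins(a, n)
        pred = nd.predicted_bin_counts(N_t, t.p_A, t.aaf)
        assert pred["N_p"].sum() == pytest.approx(N_t, abs=1e-9 * max(N_t, 1))

    def test_negative_inputs_rejected(self):
        with pytest.raises(ValueError):
            nd.predicted_bin_counts(-1, np.array([1.0]), np.array([1.0]))


class TestSubregions:
    def test_symmetric_split(self):
        mat = nd.subregion_predicted_counts(
            100, np.array([0.8, 0.2]), np.array([0.5, 0.5]), np.array([0.25, 4.0])
        )
        np.testing.assert_allclose(mat["SR1"], [10.0, 40.0])
        np.testing.assert_allclose(mat["SR1"], mat["SR2"])

    def test_single_subregion_reduces_to_whole_area(self):
        p_A, aaf = np.array([0.6, 0.4]), np.array([0.5, 1.75])
        mat = nd.subregion_predicted_counts(50, p_A, np.array([1.0]), aaf)
        base = nd.predicted_bin_counts(50, p_A, aaf)["N_p"]
        np.testing.assert_allclose(mat["SR1"], base)

    def test_marginalizes_exactly(self):
        rng = np.random.default_rng(3)
        p_SR = rng.dirichlet(np.ones(5))
        a = rng.uniform(1, 10, 10)
        n = rng.integers(1, 20, 10)
        t = _bins(a, n)
        mat = nd.subregion_predicted_counts(200, t.p_A, p_SR, t.aaf)
        base = nd.predicted_bin_counts(200, t.p_A, t.aaf)["N_p"]
        np.testing.assert_allclose(mat.sum(axis=1), base, atol=1e-9)

    def test_bad_proportions_rejected(self):
        with pytest.raises(ValueError, match="sum"):
            nd.subregion_predicted_counts(10, np.array([1.0]),
                                          np.array([0.6, 0.6]), np.array([1.0]))


class TestBoyce:
    def test_monotone_aaf_is_one(self):
        t = _bins(np.full(10, 10.0), np.arange(1, 11))
        assert nd.boyce_index(t) == pytest.approx(1.0)

    def test_antitone_aaf_is_minus_one(self):
        t = _bins(np.full(10, 10.0), np.arange(10, 0, -1))
        assert nd.boyce_index(t) == pytest.approx(-1.0)

    def test_matches_rank_correlation_oracle(self):
        def rank(v):
            order = np.argsort(v, kind="mergesort")
            r = np.empty(len(v))
            r[order] = np.arange(1, len(v) + 1)
            return r

        rng = np.random.default_rng(4)
        for _ in range(20):
            aaf = rng.permutation(np.arange(1.0, 9.0))
            t = _bins(np.full(8, 5.0), np.ones(8, dtype=int))
            t.aaf = aaf
            # Pearson correlation of ranks == Spearman (no ties here)
            ri, ra = rank(np.arange(8)), rank(aaf)
            expect = np.corrcoef(ri, ra)[0, 1]
            assert nd.boyce_index(t) == pytest.approx(expect)

    def test_undefined_below_three_bins(self):
        t = _bins([50.0, 0.0, 0.0, 50.0], [1, 0, 0, 1])
        assert np.isnan(nd.boyce_index(t))


class TestRatioTable:
    def test_constant_aaf_all_ones(self):
        r = nd.aaf_ratio_table(np.full(10, 2.5))
        np.testing.assert_allclose(r, 1.0)

    def test_undefined_lowest_bin(self):
        r = nd.aaf_ratio_table(np.array([np.nan, 1.0, 2.0]))
        assert np.isnan(r).all()
        r = nd.aaf_ratio_table(np.array([0.0, 1.0]))
        assert np.isnan(r).all()

    def test_rounding_only_at_report_time(self):
        aaf = np.array([0.1603, 2.7981])
        full = nd.aaf_ratio_table(aaf)
        rounded_in = nd.aaf_ratio_table(np.round(aaf, 3))
        assert full[1] != rounded_in[1]
        assert round(full[1], 1) == round(rounded_in[1], 1)


class TestCrossValidation:
    @staticmethod
    def _stub_fit_fn(grid, noise_by_reg):
        """Surface quality degrades with noise(reg): lets the CV mechanics
        be tested without repeated model fits."""
        base = np.tile(np.linspace(0.01, 0.99, grid.n_cols), (grid.n_rows, 1))

        def fit_fn(train_xy, reg):
            rng = np.random.default_rng(int(reg * 1000) % 2**31)
            vals = np.clip(base + rng.normal(0, noise_by_reg(reg), grid.shape), 0, 1)
            return nd.RNDSurface(grid, vals, vals, "logistic")

        return fit_fn

    def _nests(self, grid, n=80, seed=0):
        rng = np.random.default_rng(seed)
        b = grid.bounds
        # denser toward high-x (matching the stub's increasing surface)
        x = b[2] * rng.power(3, n)
        y = rng.uniform(b[1] + 1e-6, b[3], n)
        return np.column_stack([x, y])

    def test_deterministic_and_grid_default(self, small_grid):
        xy = self._nests(small_grid)
        fit_fn = self._stub_fit_fn(small_grid, lambda r: 0.05)
        a = nd.crossvalidate_regularization(fit_fn, xy, seed=5)
        b = nd.crossvalidate_regularization(fit_fn, xy, seed=5)
        pd.testing.assert_frame_equal(a.table, b.table)
        assert a.selected == b.selected
        assert a.table.reg_multiplier.tolist()[:8] == [0.1, 0.5, 0.75, 1, 2, 3, 4, 5]

    def test_ties_select_smaller_multiplier(self, small_grid):
        xy = self._nests(small_grid)
        fit_fn = self._stub_fit_fn(small_grid, lambda r: 0.0)  # reg-independent
        res = nd.crossvalidate_regularization(fit_fn, xy, seed=1)
        assert res.selected == 0.1

    def test_grid_extends_when_minimum_at_top(self, small_grid):
        # surfaces are pure noise below reg 4.5 and informative above, so
        # the minimum MSE lands on the top of the initial grid
        base = np.tile(np.linspace(0.01, 0.99, small_grid.n_cols),
                       (small_grid.n_rows, 1))

        def fit_fn(train_xy, reg):
            rng = np.random.default_rng(int(reg * 1000) % 2**31)
            if reg < 4.5:
                vals = rng.uniform(0, 1, small_grid.shape)
            else:
                vals = np.clip(base + rng.normal(0, 0.02, small_grid.shape), 0, 1)
            return nd.RNDSurface(small_grid, vals, vals, "logistic")

        xy = self._nests(small_grid)
        res = nd.crossvalidate_regularization(fit_fn, xy, seed=2)
        assert res.extended
        assert res.table.reg_multiplier.max() >= 6.0
        assert res.selected >= 5.0

    def test_too_few_nests_rejected(self, small_grid):
        with pytest.raises(ValueError, match="40"):
            nd.crossvalidate_regularization(lambda *_: None, np.zeros((10, 2)))

    def test_selected_multiplier_beats_extremes_on_real_fit(self, fitted):
        """Self-consistency on synthetic data: CV with the real estimator
        never prefers the grid extremes to the interior on a strong signal."""
        stack, covs = fitted["stack"], fitted["covs"]
        fit_fn = nd.fit_surface_factory(
            stack, fitted["background"][:1500], covs,
            mask=fitted["area"].geometry, n_hinge_knots=4,
        )
        xy = fitted["nest_set"].xy
        res = nd.crossvalidate_regularization(
            fit_fn, xy, reg_grid=(0.1, 1.0, 5.0), n_rep=3, seed=3
        )
        assert res.mse_of(res.selected) <= min(res.mse_of(0.1), res.mse_of(5.0))


class TestIndependentEvaluation:
    def test_identical_test_set_removed_by_cross_thinning(self, fitted):
        train = fitted["nest_set"]
        table = nd.bin_rnd_surface(fitted["surface"])
        table = nd.count_nests_in_bins(table, fitted["surface"], train.xy)
        table = nd.area_adjusted_frequency(table)
        with pytest.raises(ValueError, match="cross-thinning"):
            nd.evaluate_independent(train.records, train, fitted["surface"],
                                    table, d_thin_m=1000.0, buffer_m=5000.0)

    def test_independent_draw_close_to_predictions(self, landscape, fitted):
        """A fresh draw from the same nest process is predicted well: the
        observed-minus-predicted distribution concentrates near zero."""
        new = nd.simulate_nest_process(landscape["spec"], landscape["stack"],
                                       seed=99)
        train = fitted["nest_set"]
        surface = fitted["surface"]
        table = nd.bin_rnd_surface(surface)
        table = nd.count_nests_in_bins(table, surface, train.xy)
        table = nd.area_adjusted_frequency(table)
        out = nd.evaluate_independent(new, train, surface, table,
                                      d_thin_m=1000.0, buffer_m=5000.0)
        n_test = out["observed"].sum()
        assert n_test > 0
        # mean absolute per-bin error small relative to the test sample
        defined = out["defined"]
        assert out.loc[defined, "obs_minus_pred"].abs().mean() < 0.25 * n_test
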