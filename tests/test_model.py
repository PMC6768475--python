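import numpy as np
import pandas as pd
import pytest
from scipy.special import logsumexp

import nestdensity as nd
from nestdensity.features import FeatureSpec
from nestdensity.model import default_betas, fit_maxent


class TestFeatureMatrix:
    def _spec(self, bg, **kw):
        return FeatureSpec.from_background(pd.DataFrame({"x": bg}), **kw)

    def test_scaling_anchor_at_background_minimum(self):
        spec = self._spec(np.linspace(2.0, 10.0, 50))
        F = nd.build_feature_matrix(pd.DataFrame({"x": [2.0]}), spec)
        names = spec.feature_names()
        linear_quad_fwd = [i for i, n in enumerate(names)
                           if "reverse" not in n and "hinge_r" not in n]
        assert np.all(F[0, linear_quad_fwd] == 0.0)

    def test_column_cardinality_two_knots(self):
        bg = np.linspace(0, 1, 100)
        spec = self._spec(bg, n_hinge_knots=2)
        names = spec.feature_names()
        assert len(names) == 1 + 1 + 2 + 2  # linear, quadratic, 2 fwd, 2 rev

    def test_hinge_values_match_formula(self):
        bg = np.linspace(0.0, 1.0, 101)
        spec = self._spec(bg, n_hinge_knots=3)
        cf = spec.covariates["x"]
        x = np.array([0.1, 0.5, 0.9])
        F = nd.build_feature_matrix(pd.DataFrame({"x": x}), spec)
        names = spec.feature_names()
        for j, name in enumerate(names):
            if "hinge_f" in name:
                k = float(name.split("@")[1])
                np.testing.assert_allclose(F[:, j], np.maximum(0, (x - k) / (1 - k)))
            elif "hinge_r" in name:
                k = float(name.split("@")[1])
                np.testing.assert_allclose(F[:, j], np.maximum(0, (k - x) / k))

    def test_out_of_range_values_clamped(self):
        spec = self._spec(np.linspace(0.0, 1.0, 50))
        F = nd.build_feature_matrix(pd.DataFrame({"x": [-5.0, 9.0]}), spec)
        assert F.min() >= 0.0 and F.max() <= 1.0

    def test_zero_range_covariate_dropped_with_warning(self):
        with pytest.warns(UserWarning, match="zero background range"):
            spec = self._spec(np.full(20, 3.0))
        assert spec.feature_names() == []


class TestSolver:
    def test_full_shrinkage_limit(self):
        rng = np.random.default_rng(0)
        Fp = rng.uniform(0, 1, (30, 4))
        Fb = rng.uniform(0, 1, (500, 4))
        fit = fit_maxent(Fp, Fb, reg_multiplier=1e6)
        np.testing.assert_array_equal(fit.coef, 0.0)
        assert fit.training_gain == pytest.approx(0.0, abs=1e-12)
        raw = fit.raw(Fb)
        np.testing.assert_allclose(raw, 1.0 / len(Fb))

    def test_matches_bruteforce_1d_oracle(self):
        """Four background cells, one binary feature, presences at 1: the
        penalized optimum equals a dense grid search to 1e-3."""
        Fb = np.array([[1.0], [1.0], [0.0], [0.0]])
        Fp = np.ones((3, 1))
        beta = 0.05
        fit = fit_maxent(Fp, Fb, betas=np.array([beta]))
        grid = np.arange(0.0, 10.0, 1e-4)
        obj = grid - (logsumexp(np.outer(grid, [1, 1, 0, 0]), axis=1) - np.log(4)) \
            - beta * np.abs(grid)
        assert fit.coef[0] == pytest.approx(grid[np.argmax(obj)], abs=1e-3)

    def test_unpenalized_optimum_matches_presence_means(self):
        """With beta = 0 the maximum-entropy constraint holds: presence mean
        of each feature equals its model expectation (KKT stationarity)."""
        rng = np.random.default_rng(1)
        Fb = rng.uniform(0, 1, (800, 3))
        idx = rng.choice(800, 60, p=np.exp(2 * Fb[:, 0]) / np.exp(2 * Fb[:, 0]).sum())
        Fp = Fb[idx]
        fit = fit_maxent(Fp, Fb, betas=np.zeros(3), tol=1e-12)
        w = np.exp(fit.scores(Fb))
        w /= w.sum()
        np.testing.assert_allclose(Fp.mean(axis=0), w @ Fb, atol=1e-5)

    def test_kkt_inequality_with_penalties(self):
        rng = np.random.default_rng(2)
        Fb = rng.uniform(0, 1, (600, 4))
        idx = rng.choice(600, 80, p=np.exp(Fb @ [2, -1, 0, 0]) /
                         np.exp(Fb @ [2, -1, 0, 0]).sum())
        Fp = Fb[idx]
        betas = default_betas(Fp, ["linear"] * 4, 1.0)
        fit = fit_maxent(Fp, Fb, betas=betas, tol=1e-12)
        w = np.exp(fit.scores(Fb))
        w /= w.sum()
        excess = np.abs(Fp.mean(axis=0) - w @ Fb) - betas
        assert np.all(excess <= 1e-6)

    def test_raw_normalizes_over_background(self):
        rng = np.random.default_rng(3)
        Fb = rng.uniform(0, 1, (400, 3))
        Fp = Fb[rng.choice(400, 50)]
        fit = fit_maxent(Fp, Fb)
        assert fit.raw(Fb).sum() == pytest.approx(1.0, abs=1e-9)

    def test_training_gain_nonincreasing_in_regularization(self):
        rng = np.random.default_rng(4)
        Fb = rng.uniform(0, 1, (400, 3))
        idx = rng.choice(400, 60, p=np.exp(3 * Fb[:, 0]) / np.exp(3 * Fb[:, 0]).sum())
        Fp = Fb[idx]
        gains = [
            fit_maxent(Fp, Fb, reg_multiplier=r,
                       feature_classes=["linear"] * 3).training_gain
            for r in (0.1, 0.5, 0.75, 1, 2, 3, 4, 5)
        ]
        assert all(a >= b - 1e-9 for a, b in zip(gains, gains[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError, match="presence"):
            fit_maxent(np.empty((0, 2)), np.ones((10, 2)))
        with pytest.raises(ValueError, match="background"):
            fit_maxent(np.ones((10, 2)), np.ones((5, 2)))


class TestContributions:
    def test_single_covariate_is_100(self, fitted):
        est = nd.MaxentDensityEstimator(n_hinge_knots=4)
        X = fitted["X"][["topographic_1"]]
        est.fit(X, fitted["y"])
        assert est.contributions_["topographic_1"] == pytest.approx(100.0)

    def test_sum_to_100_and_dominant_covariate_ranks_first(self, fitted):
        contrib = fitted["estimator"].contributions_
        assert sum(contrib.values()) == pytest.approx(100.0, abs=1e-6)
        # nests were simulated from topographic_1 only
        assert max(contrib, key=contrib.get) == "topographic_1"


class TestReduceAndRefit:
    def test_below_threshold_removed(self, fitted):
        est, X, y = fitted["estimator"], fitted["X"], fitted["y"]
        contrib = est.contributions_
        reduced = nd.reduce_and_refit(est, X, y, threshold_pct=1.0)
        expect = {c for c, v in contrib.items() if v >= 1.0}
        assert set(reduced.feature_spec_.covariates) == expect

    def test_noop_when_all_contribute(self):
        rng = np.random.default_rng(5)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 400)})
        y = np.r_[np.ones(40), np.zeros(360)]
        X.loc[:39, "a"] = rng.uniform(0.7, 1, 40)
        est = nd.MaxentDensityEstimator(n_hinge_knots=2).fit(X, y)
        reduced = nd.reduce_and_refit(est, X, y)
        assert set(reduced.feature_spec_.covariates) == {"a"}

    def test_reduced_gain_close_to_initial(self, fitted):
        est, X, y = fitted["estimator"], fitted["X"], fitted["y"]
        reduced = nd.reduce_and_refit(est, X, y, threshold_pct=1.0)
        assert reduced.training_gain_ >= 0.98 * est.training_gain_


class TestEstimatorAPI:
    def test_sklearn_contract(self, fitted):
        from sklearn.base import clone

        est = fitted["estimator"]
        params = est.get_params()
        assert params["reg_multiplier"] == 1.0
        clone(est)
        est2 = nd.MaxentDensityEstimator(**params)
        assert est2.get_params() == params

    def test_requires_binary_y(self):
        X = pd.DataFrame({"a": np.linspace(0, 1, 10)})
        with pytest.raises(ValueError, match="binary"):
            nd.MaxentDensityEstimator().fit(X, np.arange(10))

    def test_logistic_monotone_in_raw(self, fitted):
        est, X = fitted["estimator"], fitted["X"]
        raw = est.predict_raw(X)
        logistic = est.predict(X, transform="logistic")
        order = np.argsort(raw)
        assert np.all(np.diff(logistic[order]) >= -1e-15)
        assert logistic.min() >= 0.0 and logistic.max() <= 1.0

    def test_uniform_model_constant_logistic(self):
        rng = np.random.default_rng(6)
        X = pd.DataFrame({"a": rng.uniform(0, 1, 300)})
        y = np.r_[np.ones(30), np.zeros(270)]
        est = nd.MaxentDensityEstimator(reg_multiplier=1e6).fit(X, y)
        p = est.predict(X)
        np.testing.assert_allclose(p, 0.5, atol=1e-9)

    def test_json_roundtrip_preserves_predictions(self, fitted, tmp_path):
        est, X = fitted["estimator"], fitted["X"]
        path = tmp_path / "model.json"
        est.to_json(path)
        est2 = nd.MaxentDensityEstimator.from_json(path)
        np.testing.assert_allclose(est2.predict_raw(X), est.predict_raw(X))
        np.testing.assert_allclose(est2.predict(X), est.predict(X))


class TestSurface:
    def test_values_bounded_and_raw_retained(self, fitted):
        surf = fitted["surface"]
        vals = surf.values[np.isfinite(surf.values)]
        assert vals.min() >= 0.0 and vals.max() <= 1.0
        assert np.isfinite(surf.raw).sum() == np.isfinite(surf.values).sum()

    def test_missing_covariate_named(self, fitted):
        stack = fitted["stack"].subset(["topographic_1"])
        with pytest.raises(KeyError, match="topographic_2"):
            nd.predict_rnd(fitted["estimator"], stack)

    def test_parameter_recovery_against_true_intensity(self, landscape, fitted):
        """Fitted raw intensity ranks cells like the simulating intensity."""
        from scipy.stats import spearmanr

        lam = nd.intensity_grid(landscape["spec"], landscape["stack"])
        surf = fitted["surface"]
        ok = np.isfinite(surf.raw)
        rho = spearmanr(surf.raw[ok], lam[ok]).statistic
        assert rho >= 0.9
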