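import itertools

import numpy as np
import pytest
from sklearn.linear_model import ElasticNet

from ecocorr import (BatteryConfig, PanelError, bootstrap_treatment,
                     cross_validate, enet_fit, fit_path, lambda_grid,
                     lasso_fit, ridge_fit, standardize, top5_frequency,
                     twelve_model_battery)
from ecocorr.penalized import ModelRecord, PenalizedFit, _objective


def _toy(seed=0, n=40, p=3, sigma=0.3):
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, p))
    beta = np.zeros(p)
    beta[0] = 1.0
    y = X @ beta + sigma * rng.standard_normal(n)
    Xs, ys, _ = standardize(X, y)
    return Xs, ys


class TestStandardize:
    def test_idempotent_on_standardized_input(self, rng):
        X = rng.standard_normal((50, 4))
        y = rng.standard_normal(50)
        Xs, ys, _ = standardize(X, y)
        Xs2, ys2, _ = standardize(Xs, ys)
        np.testing.assert_allclose(Xs2, Xs, atol=1e-12)
        np.testing.assert_allclose(ys2, ys, atol=1e-12)

    def test_back_transform_inverse(self, rng):
        X = rng.uniform(5, 500, (20, 3))
        y = rng.uniform(0, 10, 20)
        Xs, _, scaler = standardize(X, y)
        np.testing.assert_allclose(scaler.back_transform(Xs), X, rtol=1e-12)

    def test_constant_column_named(self, rng):
        X = rng.standard_normal((10, 3))
        X[:, 1] = 4.0
        with pytest.raises(PanelError, match="beer"):
            standardize(X, rng.standard_normal(10), names=["a", "beer", "c"])

    def test_beta_ranking_invariant_to_units(self, rng):
        """Rescaling a predictor's units must not change standardized-beta
        rankings."""
        X = rng.standard_normal((60, 4))
        y = X @ np.array([0.9, -0.5, 0.3, 0.1]) + 0.2 * rng.standard_normal(60)
        Xs, ys, _ = standardize(X, y)
        rank1 = np.argsort(-np.abs(ridge_fit(Xs, ys, 0.1).beta))
        X2 = X * np.array([1000.0, 0.001, 1.0, 17.0])
        Xs2, ys2, _ = standardize(X2, y)
        rank2 = np.argsort(-np.abs(ridge_fit(Xs2, ys2, 0.1).beta))
        np.testing.assert_array_equal(rank1, rank2)


class TestRidge:
    def test_zero_penalty_equals_ols(self):
        Xs, ys = _toy()
        ols = np.linalg.lstsq(Xs, ys, rcond=None)[0]
        np.testing.assert_allclose(ridge_fit(Xs, ys, 0.0).beta, ols, atol=1e-8)

    @pytest.mark.parametrize("lam", [0.05, 0.5, 3.0])
    def test_single_predictor_closed_form(self, lam, rng):
        x = rng.standard_normal((30, 1))
        y = 0.7 * x[:, 0] + 0.2 * rng.standard_normal(30)
        Xs, ys, _ = standardize(x, y)
        n = len(ys)
        expected = (Xs[:, 0] @ ys / n) / (Xs[:, 0] @ Xs[:, 0] / n + lam)
        fit = ridge_fit(Xs, ys, lam)
        assert fit.beta[0] == pytest.approx(expected, rel=1e-10)
        # grid-minimization oracle around the closed form
        grid = np.linspace(expected - 0.5, expected + 0.5, 2001)
        objs = [_objective(Xs, ys, np.array([b]), lam, 0.0) for b in grid]
        assert fit.objective <= min(objs) + 1e-9

    def test_norm_shrinks_monotonically(self):
        Xs, ys = _toy()
        norms = [np.linalg.norm(ridge_fit(Xs, ys, lam).beta)
                 for lam in (0.0, 0.1, 1.0, 10.0, 1e3)]
        assert norms == sorted(norms, reverse=True)
        assert norms[-1] < 1e-3


class TestElasticNet:
    def test_alpha_zero_matches_ridge(self):
        Xs, ys = _toy(p=5)
        for lam in (0.01, 0.3):
            np.testing.assert_allclose(enet_fit(Xs, ys, lam, 0.0).beta,
                                       ridge_fit(Xs, ys, lam).beta, atol=1e-8)

    @pytest.mark.parametrize("lam", [0.02, 0.2, 0.8])
    def test_lasso_single_predictor_soft_threshold(self, lam, rng):
        x = rng.standard_normal((40, 1))
        y = 0.5 * x[:, 0] + 0.3 * rng.standard_normal(40)
        Xs, ys, _ = standardize(x, y)
        n = len(ys)
        rho = Xs[:, 0] @ ys / n
        expected = np.sign(rho) * max(abs(rho) - lam, 0) / (Xs[:, 0] @ Xs[:, 0] / n)
        fit = lasso_fit(Xs, ys, lam)
        assert fit.beta[0] == pytest.approx(expected, abs=1e-10)
        # fine grid search oracle
        grid = np.linspace(-1.5, 1.5, 6001)
        objs = [_objective(Xs, ys, np.array([b]), lam, 1.0) for b in grid]
        assert fit.objective <= min(objs) + 1e-8

    @pytest.mark.parametrize("lam,alpha", [(0.05, 0.5), (0.2, 0.3),
                                           (0.5, 0.9), (0.02, 1.0)])
    def test_objective_beats_exhaustive_grid(self, lam, alpha):
        """Solver objective within 1e-6 of the exhaustive grid minimum on a
        3-predictor toy."""
        Xs, ys = _toy(seed=3)
        fit = enet_fit(Xs, ys, lam, alpha)
        axis = np.linspace(-1.4, 1.4, 57)
        best = np.inf
        n = len(ys)
        for b in itertools.product(axis, axis, axis):
            b = np.array(b)
            r = ys - Xs @ b
            obj = (r @ r / (2 * n)
                   + lam * (alpha * np.abs(b).sum() + 0.5 * (1 - alpha) * b @ b))
            best = min(best, obj)
        assert fit.objective <= best + 1e-6

    def test_matches_sklearn_coordinate_descent(self):
        """Independent cross-check: scikit-learn uses the same 1/(2n)
        objective scale."""
        Xs, ys = _toy(seed=5, n=60, p=6, sigma=0.4)
        for lam, alpha in ((0.05, 0.5), (0.2, 1.0), (0.1, 0.25)):
            ours = enet_fit(Xs, ys, lam, alpha).beta
            ref = ElasticNet(alpha=lam, l1_ratio=alpha, fit_intercept=False,
                             tol=1e-10, max_iter=100000).fit(Xs, ys).coef_
            np.testing.assert_allclose(ours, ref, atol=1e-5)

    def test_objective_non_increasing_every_sweep(self):
        Xs, ys = _toy(seed=9, p=8, sigma=0.8)
        lam, alpha = 0.1, 0.5
        beta = np.zeros(8)
        objs = [_objective(Xs, ys, beta, lam, alpha)]
        from ecocorr.penalized import _cd_sweeps
        G, c = Xs.T @ Xs / len(ys), Xs.T @ ys / len(ys)
        for _ in range(25):
            _cd_sweeps(G, c, lam * alpha, lam * (1 - alpha), beta, 0.0, 1)
            objs.append(_objective(Xs, ys, beta, lam, alpha))
        assert all(b <= a + 1e-12 for a, b in zip(objs, objs[1:]))

    def test_bad_hyperparameters_error(self):
        Xs, ys = _toy()
        with pytest.raises(PanelError):
            enet_fit(Xs, ys, -0.1, 0.5)
        with pytest.raises(PanelError):
            enet_fit(Xs, ys, 0.1, 1.5)


class TestLasso:
    def test_lambda_max_kkt_zeroes_everything(self):
        Xs, ys = _toy(p=6)
        lam_max = np.abs(Xs.T @ ys).max() / len(ys)
        assert np.all(lasso_fit(Xs, ys, lam_max * 1.0001).beta == 0)
        assert np.any(lasso_fit(Xs, ys, lam_max * 0.99).beta != 0)

    def test_support_shrinks_along_path_on_toy(self):
        Xs, ys = _toy(seed=11, p=5, sigma=0.5)
        lambdas = lambda_grid(Xs, ys, 1.0, n_lambda=40)
        betas = fit_path(Xs, ys, "lasso", lambdas)
        nnz = (betas != 0).sum(axis=1)
        assert np.all(np.diff(nnz) >= 0)  # grid descends, support grows

    def test_zero_penalty_equals_ols(self):
        Xs, ys = _toy(seed=2)
        ols = np.linalg.lstsq(Xs, ys, rcond=None)[0]
        np.testing.assert_allclose(lasso_fit(Xs, ys, 0.0).beta, ols, atol=1e-7)

    def test_warm_path_matches_cold_fits(self):
        Xs, ys = _toy(seed=4, p=6)
        lambdas = lambda_grid(Xs, ys, 1.0, n_lambda=25)
        betas = fit_path(Xs, ys, "lasso", lambdas)
        for i in (0, 7, 24):
            cold = lasso_fit(Xs, ys, lambdas[i]).beta
            np.testing.assert_allclose(betas[i], cold, atol=1e-6)


class TestCrossValidate:
    def test_pure_noise_prefers_heavy_penalty(self):
        """Null outcome: the CV-optimal lasso keeps (almost) nothing."""
        hits = 0
        reps = 200
        for s in range(reps):
            rng = np.random.default_rng(s)
            X = rng.standard_normal((30, 5))
            y = rng.standard_normal(30)
            sel = cross_validate(X, y, "lasso", k_folds=5, seed=s)
            Xs, ys, _ = standardize(X, y)
            beta = lasso_fit(Xs, ys, sel.lambda_optimal).beta
            upper_half = sel.lambda_optimal >= np.median(sel.lambdas)
            hits += upper_half and np.max(np.abs(beta), initial=0.0) < 0.5
        assert hits >= 0.9 * reps

    def test_strong_signal_predictor_survives(self):
        hits = 0
        reps = 50
        for s in range(reps):
            rng = np.random.default_rng(1000 + s)
            X = rng.standard_normal((40, 8))
            y = 1.0 * X[:, 2] + 0.3 * rng.standard_normal(40)
            sel = cross_validate(X, y, "lasso", k_folds=5, seed=s)
            Xs, ys, _ = standardize(X, y)
            beta = lasso_fit(Xs, ys, sel.lambda_optimal).beta
            hits += beta[2] != 0
        assert hits >= 0.95 * reps

    def test_error_curve_stable_across_fold_seeds(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((60, 5))
        y = X[:, 0] + 0.5 * rng.standard_normal(60)
        s1 = cross_validate(X, y, "lasso", k_folds=10, seed=1)
        s2 = cross_validate(X, y, "lasso", k_folds=10, seed=2)
        assert np.max(np.abs(s1.mean_error - s2.mean_error)) < 0.2

    def test_parsimonious_at_least_optimal_penalty(self):
        Xs, ys = _toy(seed=8, n=50, p=6)
        sel = cross_validate(Xs, ys, "enet", k_folds=5, seed=0)
        assert sel.lambda_parsimonious >= sel.lambda_optimal

    def test_tiny_folds_error(self):
        Xs, ys = _toy(n=12)
        with pytest.raises(PanelError, match="fold"):
            cross_validate(Xs, ys, "lasso", k_folds=10, seed=0)


class TestBootstrap:
    def test_mean_beta_converges_on_noiseless_data(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((50, 4))
        y = X @ np.array([1.0, -0.5, 0.0, 0.0])  # noiseless
        Xs, ys, _ = standardize(X, y)
        lambdas = lambda_grid(Xs, ys, 1.0, n_lambda=30)
        full = fit_path(Xs, ys, "lasso", lambdas)
        sel, mean_beta = bootstrap_treatment(X, y, "lasso", lambdas, B=400,
                                             seed=0)
        i = 15
        np.testing.assert_allclose(mean_beta[i], full[i], atol=0.08)

    def test_identical_seed_identical_output(self):
        rng = np.random.default_rng(6)
        X = rng.standard_normal((30, 4))
        y = X[:, 0] + 0.3 * rng.standard_normal(30)
        a = bootstrap_treatment(X, y, "lasso", B=60, seed=9)
        b = bootstrap_treatment(X, y, "lasso", B=60, seed=9)
        np.testing.assert_array_equal(a[1], b[1])
        np.testing.assert_array_equal(a[0].mean_error, b[0].mean_error)

    def test_oob_selection_rules_ordered(self):
        rng = np.random.default_rng(7)
        X = rng.standard_normal((40, 5))
        y = X[:, 1] + 0.4 * rng.standard_normal(40)
        sel, _ = bootstrap_treatment(X, y, "enet", B=80, seed=0)
        assert sel.lambda_parsimonious >= sel.lambda_optimal


@pytest.fixture(scope="module")
def battery():
    rng = np.random.default_rng(12)
    X = rng.standard_normal((35, 10))
    y = X[:, 0] - 0.8 * X[:, 5] + 0.4 * rng.standard_normal(35)
    cfg = BatteryConfig(n_boot=40, k_folds=5)
    return twelve_model_battery(X, y, cfg, seed=3), X, y, cfg


class TestBattery:

    def test_twelve_models_six_optimal(self, battery):
        records, *_ = battery
        assert len(records) == 12
        assert sum(r.rule == "optimal" for r in records) == 6

    def test_labels_unique_and_complete(self, battery):
        records, *_ = battery
        labels = {r.label for r in records}
        assert len(labels) == 12
        for m in ("ridge", "lasso", "enet"):
            for t in ("cross_validation", "bootstrap"):
                for rule in ("optimal", "parsimonious"):
                    assert f"{m}/{t}/{rule}" in labels

    def test_deterministic_under_seed(self, battery):
        records, X, y, cfg = battery
        again = twelve_model_battery(X, y, cfg, seed=3)
        for a, b in zip(records, again):
            np.testing.assert_array_equal(a.fit.beta, b.fit.beta)
            assert a.fit.lam == b.fit.lam


class TestTop5Frequency:
    def _records(self, betas, rules=None):
        recs = []
        for i, b in enumerate(betas):
            rule = (rules[i] if rules else ("optimal" if i % 2 == 0
                                            else "parsimonious"))
            sel = None
            recs.append(ModelRecord("lasso", "cross_validation", rule, sel,
                                    PenalizedFit("lasso", 0.1, 1.0,
                                                 np.asarray(b, float), 0.0, 0.0)))
        return recs

    def test_five_predictors_always_nonzero_saturate(self):
        betas = [np.arange(1, 6, dtype=float)] * 12
        rules = ["optimal"] * 6 + ["parsimonious"] * 6
        table = top5_frequency(self._records(betas, rules), list("abcde"))
        assert (table["count_total"] == 12).all()
        assert (table["count_optimal"] == 6).all()

    def test_zero_beta_never_counted(self):
        betas = [[1.0, 0.0, 2.0]] * 12
        table = top5_frequency(self._records(betas), list("abc")).set_index("variable")
        assert table.loc["b", "count_total"] == 0
        assert table.loc["b", "sign"] == ""

    def test_sign_labels(self):
        betas = [[1.0, -1.0, 1.0], [2.0, -2.0, -1.0]]
        table = top5_frequency(self._records(betas, ["optimal", "optimal"]),
                               list("abc")).set_index("variable")
        assert table.loc["a", "sign"] == "positive"
        assert table.loc["b", "sign"] == "negative"
        assert table.loc["c", "sign"] == "mixed"

    def test_counts_bounded(self, battery_table=None):
        betas = [np.linspace(1, 2, 8)] * 12
        table = top5_frequency(self._records(betas,
                                             ["optimal"] * 6 + ["parsimonious"] * 6),
                               [f"v{i}" for i in range(8)])
        assert table["count_total"].max() <= 12
        assert table["count_optimal"].max() <= 6
        assert (table["count_optimal"] <= table["count_total"]).all()
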