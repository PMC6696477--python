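"""Calibrators: BPNN selection protocol, SVR grid search, PLSR factors."""

import numpy as np
import pandas as pd
import pytest

from aossom.calibrate import (BPNNConfig, BPNNModel, Dataset, PLSRConfig,
                              PLSRModel, SVRConfig, SVRModel, aic, fit_plsr,
                              hidden_range_from_rule, select_hidden_from_table,
                              select_pcfs, train_bpnn, train_svr)
from aossom.evaluation import r2_corr
from aossom.exceptions import (DegenerateInputError, LengthError,
                               ParameterError)
from aossom.fixtures import load_bpnn_selection_table


@pytest.fixture
def linear_dataset(rng):
    """71 noiseless samples of a linear map on 40 standardized features."""
    X = rng.normal(size=(71, 40))
    w = rng.normal(size=40)
    return Dataset(X=X, y=X @ w * 0.5 + 23.0)


class TestHiddenRange:
    def test_override_replaces_rule(self):
        assert hidden_range_from_rule(40, 1, (1, 10),
                                      override=(6, 16)) == list(range(6, 17))

    def test_exact_square_single_alpha(self):
        assert hidden_range_from_rule(3, 1, (1, 1)) == [3]

    def test_rule_evaluation(self):
        assert hidden_range_from_rule(8, 1, (1, 2)) == [4, 5]

    def test_forty_inputs_rule_without_override(self):
        # round(sqrt(41)) = 6, alpha 1..10
        assert hidden_range_from_rule(40, 1, (1, 10)) == list(range(7, 17))

    def test_empty_override_rejected(self):
        with pytest.raises(ParameterError):
            hidden_range_from_rule(40, 1, override=(10, 6))


class TestTrainBpnn:
    def test_constant_target_learned(self, rng):
        X = rng.normal(size=(30, 5))
        data = Dataset(X=X, y=np.full(30, 21.5))
        result = train_bpnn(data, h=4, seed=1)
        np.testing.assert_allclose(result.predict(X), 21.5, atol=0.1)

    def test_seeded_determinism(self, linear_dataset):
        cfg = BPNNConfig(max_iterations=200)
        a = train_bpnn(linear_dataset, h=6, config=cfg, seed=5)
        b = train_bpnn(linear_dataset, h=6, config=cfg, seed=5)
        np.testing.assert_array_equal(a.predict(linear_dataset.X),
                                      b.predict(linear_dataset.X))

    def test_noiseless_linear_map_converges(self, linear_dataset):
        result = train_bpnn(linear_dataset, h=6, seed=2)
        resid = result.predict(linear_dataset.X) - linear_dataset.y
        assert np.sqrt(np.mean(resid ** 2)) < 0.05 * linear_dataset.y.std()

    def test_feature_width_checked_at_predict(self, linear_dataset):
        from aossom.exceptions import ModelCompatibilityError
        result = train_bpnn(linear_dataset, h=3,
                            config=BPNNConfig(max_iterations=50))
        with pytest.raises(ModelCompatibilityError):
            result.predict(np.zeros((2, 39)))


class TestSelectHiddenSize:
    def test_published_selection_grid_yields_six(self):
        table = load_bpnn_selection_table()
        assert select_hidden_from_table(table) == 6

    def test_r2_has_priority_over_rmse(self):
        table = pd.DataFrame({
            "h": [7, 8],
            "r2_mean": [0.9, 0.8],
            "rmse_mean": [5.0, 4.0],
        })
        assert select_hidden_from_table(table) == 7

    def test_ties_break_to_smaller_h(self):
        table = pd.DataFrame({
            "h": [9, 8],
            "r2_mean": [0.9, 0.9],
            "rmse_mean": [5.0, 5.0],
        })
        assert select_hidden_from_table(table) == 8

    def test_single_candidate_selected(self, linear_dataset):
        model = BPNNModel(linear_dataset,
                          BPNNConfig(hidden_range=(6, 6), repeats=2,
                                     max_iterations=100))
        table = model.selection_table()
        assert select_hidden_from_table(table) == 6
        assert set(table["h"]) == {6}

    def test_selection_table_has_min_max_mean(self, linear_dataset):
        model = BPNNModel(linear_dataset,
                          BPNNConfig(hidden_range=(6, 7), repeats=3,
                                     max_iterations=100))
        table = model.selection_table()
        assert {"r2_min", "r2_max", "r2_mean",
                "rmse_min", "rmse_max", "rmse_mean"} <= set(table.columns)
        assert (table["r2_min"] <= table["r2_mean"]).all()
        assert (table["r2_mean"] <= table["r2_max"]).all()


@pytest.fixture
def smooth_dataset(rng):
    """Small smooth nonlinear regression problem for the SVR search."""
    X = rng.uniform(-1, 1, size=(40, 3))
    y = np.sin(2 * X[:, 0]) + X[:, 1] ** 2 + 20.0
    return Dataset(X=X, y=y)


class TestSvr:
    def test_constant_targets_inside_tube(self, rng):
        X = rng.normal(size=(20, 4))
        data = Dataset(X=X, y=np.full(20, 19.0))
        result = train_svr(data, C=10.0, sigma2=1.0)
        np.testing.assert_allclose(result.predict(X), 19.0, atol=1e-6)

    def test_nonpositive_hyperparameters_rejected(self, smooth_dataset):
        with pytest.raises(ParameterError):
            train_svr(smooth_dataset, C=-1.0, sigma2=1.0)
        with pytest.raises(ParameterError):
            train_svr(smooth_dataset, C=1.0, sigma2=0.0)

    def test_tracks_toy_curve_within_tube_plus_slack(self):
        x = np.linspace(0, 1, 10)[:, None]
        y = 2.0 * x.ravel() + 1.0
        data = Dataset(X=x, y=y)
        result = train_svr(data, C=1000.0, sigma2=0.5)
        # kernel-ridge oracle on the same 10 points
        from scipy.linalg import solve
        K = np.exp(-(x - x.T) ** 2 / (2 * 0.5))
        alpha = solve(K + 1e-6 * np.eye(10), y - y.mean())
        oracle = K @ alpha + y.mean()
        eps = 0.1
        assert np.max(np.abs(result.predict(x) - y)) < eps + 0.05
        assert np.max(np.abs(oracle - y)) < 0.05  # oracle sanity

    def test_duplicating_rows_leaves_predictions_unchanged(self, smooth_dataset):
        result = train_svr(smooth_dataset, C=10.0, sigma2=1.0)
        doubled = Dataset(X=np.vstack([smooth_dataset.X] * 2),
                          y=np.concatenate([smooth_dataset.y] * 2))
        result2 = train_svr(doubled, C=10.0, sigma2=1.0)
        np.testing.assert_allclose(result2.predict(smooth_dataset.X),
                                   result.predict(smooth_dataset.X),
                                   atol=1e-6)

    def test_single_cell_grid_returns_that_cell(self, smooth_dataset):
        cfg = SVRConfig(coarse_range=(2, 2), coarse_step=1.0,
                        fine_step=0.25, fine_halfwidth=0.0, folds=4)
        C, sigma2, _ = SVRModel(smooth_dataset, cfg).grid_search()
        assert C == pytest.approx(4.0)
        assert sigma2 == pytest.approx(4.0)

    def test_fine_stage_never_worse_than_coarse(self, smooth_dataset):
        cfg = SVRConfig(coarse_range=(-8, 8), coarse_step=4.0,
                        fine_halfwidth=2.0, folds=4, seed=3)
        _, _, surfaces = SVRModel(smooth_dataset, cfg).grid_search()
        coarse_best = surfaces["coarse"].to_numpy().min()
        fine_best = surfaces["fine"].to_numpy().min()
        assert fine_best <= coarse_best + 1e-12

    def test_search_is_seed_deterministic(self, smooth_dataset):
        cfg = SVRConfig(coarse_range=(-4, 4), coarse_step=4.0,
                        fine_halfwidth=1.0, folds=4, seed=9)
        a = SVRModel(smooth_dataset, cfg).grid_search()
        b = SVRModel(smooth_dataset, cfg).grid_search()
        assert a[0] == b[0] and a[1] == b[1]
        pd.testing.assert_frame_equal(a[2]["coarse"], b[2]["coarse"])


@pytest.fixture
def latent_dataset(rng):
    """71 samples from a 4-latent-factor linear generative model, low noise.

    Distinct factor scales and orthonormal loadings keep the generative
    rank identifiable from leave-one-out error.
    """
    gen = np.random.default_rng(42)
    n, k, q = 71, 40, 4
    T = gen.normal(size=(n, q)) * np.array([4.0, 3.0, 2.0, 1.0])
    P = np.linalg.qr(gen.normal(size=(k, q)))[0].T
    X = T @ P + 0.01 * gen.normal(size=(n, k))
    y = T @ np.ones(q) + 23.0 + 0.3 * gen.normal(size=n)
    return Dataset(X=X, y=y)


class TestPlsr:
    def test_rank_one_target_recovered_with_one_factor(self, rng):
        # orthogonal zero-mean predictors: one factor then recovers a
        # single-predictor target exactly
        raw = rng.normal(size=(30, 6))
        X = np.linalg.qr(raw - raw.mean(axis=0))[0]
        y = 3.0 * X[:, 2]
        result = fit_plsr(Dataset(X=X, y=y), n_factors=1)
        np.testing.assert_allclose(result.predict(X), y, atol=1e-8)

    def test_full_rank_equals_least_squares_oracle(self, rng):
        X = rng.normal(size=(25, 5))
        y = rng.normal(size=25) + 20.0
        result = fit_plsr(Dataset(X=X, y=y), n_factors=5)
        design = np.column_stack([np.ones(25), X])
        beta, *_ = np.linalg.lstsq(design, y, rcond=None)
        np.testing.assert_allclose(result.predict(X), design @ beta,
                                   atol=1e-6)

    def test_zero_variance_column_rejected(self, rng):
        X = rng.normal(size=(20, 4))
        X[:, 1] = 2.0
        with pytest.raises(DegenerateInputError):
            fit_plsr(Dataset(X=X, y=rng.normal(size=20)), n_factors=2)

    def test_pure_noise_predictor_perturbs_one_factor_fit_boundedly(self, rng):
        n = 2000  # large n keeps the noise column's sample corr with y small
        raw = rng.normal(size=(n, 6))
        X = np.linalg.qr(raw - raw.mean(axis=0))[0]
        y = X @ np.array([1.0, -2.0, 0.5, 0.0, 0.0, 0.0]) + 25.0
        base = fit_plsr(Dataset(X=X, y=y), 1).predict(X)
        X_aug = np.column_stack([X, rng.normal(size=n)])
        aug = fit_plsr(Dataset(X=X_aug, y=y), 1).predict(X_aug)
        assert np.max(np.abs(aug - base)) < 0.1 * y.std()

    def test_aic_worked_values(self):
        assert aic(71, 100.0, 4) == pytest.approx(334.967, abs=5e-4)
        assert aic(12345, 1.0, 0) == pytest.approx(0.0)

    def test_select_pcfs_recovers_generative_rank(self, latent_dataset):
        p, rmsecv_curve, aic_curve = select_pcfs(latent_dataset,
                                                 PLSRConfig(max_factors=10))
        assert p == 4
        assert list(rmsecv_curve.columns) == ["p", "rmsecv"]
        assert list(aic_curve.columns) == ["p", "aic"]

    def test_single_candidate_degenerate_argmin(self, latent_dataset):
        p, _, _ = select_pcfs(latent_dataset, PLSRConfig(max_factors=1))
        assert p == 1

    def test_max_factors_truncated_to_rank_with_warning(self, rng):
        base = rng.normal(size=(10, 2))
        X = np.column_stack([base, base[:, 0] + base[:, 1]])  # rank 2
        data = Dataset(X=X, y=rng.normal(size=10))
        with pytest.warns(UserWarning, match="truncated"):
            PLSRModel(data, PLSRConfig(max_factors=3)).select_factors()


class TestPredictPurity:
    def test_each_calibrator_predicts_deterministically(self, linear_dataset):
        fits = [
            train_bpnn(linear_dataset, 4, BPNNConfig(max_iterations=100),
                       seed=0),
            train_svr(linear_dataset, 10.0, 1.0),
            fit_plsr(linear_dataset, 3),
        ]
        probe = linear_dataset.X[:7]
        for fitted in fits:
            np.testing.assert_array_equal(fitted.predict(probe),
                                          fitted.predict(probe))
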