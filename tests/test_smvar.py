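"""Sparse MVAR estimation: lagged design, MM solver, selection criteria."""

import warnings

import numpy as np
import pytest
from sklearn.linear_model import Lasso

from eegstates.data import TrialTensor
from eegstates.smvar import (
    MVARModel,
    SparseMVAR,
    WindowSpec,
    bic_score,
    build_lagged_regression,
    default_lambda_grid,
    fit_lasso_mm,
    fit_ols,
    gcv_score,
    network_from_coefficients,
    select_lambda,
    select_order,
    window_networks,
)


def ar_realization(A, n, rng, burn=200, obs_noise=0.0):
    """(n, m) realization of y_t = A y_{t-1} + e with unit innovations."""
    m = A.shape[0]
    y = rng.standard_normal(m)
    out = np.empty((n, m))
    for t in range(-burn, n):
        y = A @ y + rng.standard_normal(m)
        if t >= 0:
            out[t] = y
    if obs_noise:
        out = out + obs_noise * rng.standard_normal(out.shape)
    return out


class TestLaggedDesign:
    def test_row_counts_single_segment(self, rng):
        X, Y = build_lagged_regression([rng.standard_normal((12, 28))], p=1)
        assert X.shape == (11, 28) and Y.shape == (11, 28)

    def test_rows_exclude_segment_boundaries(self, rng):
        segs = [rng.standard_normal((12, 3)) for _ in range(10)]
        X, Y = build_lagged_regression(segs, p=1)
        assert X.shape[0] == 110  # 10 segments x (12 - 1), no boundary rows

    def test_lag_major_column_order(self, rng):
        seg = rng.standard_normal((10, 2))
        X, Y = build_lagged_regression([seg], p=2)
        c = seg - seg.mean(axis=0)
        np.testing.assert_allclose(X[0], [c[1, 0], c[1, 1], c[0, 0], c[0, 1]])
        np.testing.assert_allclose(Y[0], c[2])

    def test_order_equal_to_width_raises(self, rng):
        with pytest.raises(ValueError, match="samples"):
            build_lagged_regression([rng.standard_normal((3, 2))], p=3)


class TestOls:
    def test_identity_design(self, rng):
        Y = rng.standard_normal((5, 3))
        np.testing.assert_allclose(fit_ols(np.eye(5)[:, :5], Y), Y)

    def test_noiseless_ar1_recovery(self, rng):
        data = ar_realization(np.array([[0.5]]), 200, rng)
        # noiseless autoregression: regressing y_t on y_{t-1} is exact up to
        # innovation noise; with the innovations as the only noise the OLS
        # estimate concentrates around 0.5
        X, Y = build_lagged_regression([data], p=1)
        a = fit_ols(X, Y)[0, 0]
        assert abs(a - 0.5) < 0.1
        # a literally noise-free linear map is recovered exactly
        Xd = rng.standard_normal((50, 4))
        A = rng.standard_normal((4, 2))
        np.testing.assert_allclose(fit_ols(Xd, Xd @ A), A, atol=1e-6)

    def test_duplicated_column_raises(self, rng):
        X = rng.standard_normal((20, 3))
        X[:, 2] = X[:, 0]
        with pytest.raises(np.linalg.LinAlgError, match="lam"):
            fit_ols(X, rng.standard_normal((20, 2)))


class TestLassoMM:
    def test_lam_zero_equals_ols(self, rng):
        X = rng.standard_normal((40, 6))
        Y = rng.standard_normal((40, 4))
        np.testing.assert_allclose(fit_lasso_mm(X, Y, 0.0), fit_ols(X, Y), atol=1e-6)

    def test_huge_lam_gives_zero(self, rng):
        X = rng.standard_normal((40, 6))
        Y = rng.standard_normal((40, 4))
        assert np.abs(fit_lasso_mm(X, Y, 1e6)).max() == 0.0

    def test_orthonormal_soft_threshold(self, rng):
        Q, _ = np.linalg.qr(rng.standard_normal((60, 60)))
        X = Q[:, :8]
        Y = rng.standard_normal((60, 3))
        lam = 0.7
        ols = X.T @ Y
        expected = np.sign(ols) * np.maximum(np.abs(ols) - lam**2 / 2, 0.0)
        np.testing.assert_allclose(fit_lasso_mm(X, Y, lam), expected, atol=1e-4)

    @pytest.mark.parametrize("seed", [0, 1, 2, 3, 4])
    def test_matches_coordinate_descent(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((40, 5))
        Y = rng.standard_normal((40, 5))
        lam = 10 ** rng.uniform(-1, 0.5)
        ours = fit_lasso_mm(X, Y, lam)
        cd = Lasso(alpha=lam**2 / (2 * X.shape[0]), fit_intercept=False,
                   tol=1e-12, max_iter=100000).fit(X, Y)
        np.testing.assert_allclose(ours, cd.coef_.T, atol=1e-4)

    def test_objective_monotone_nonincreasing(self, rng):
        X = rng.standard_normal((50, 8))
        Y = rng.standard_normal((50, 4))
        _, info = fit_lasso_mm(X, Y, 1.3, return_info=True)
        obj = np.array(info["objective"])
        assert np.all(np.diff(obj) <= 1e-9 * np.abs(obj[:-1]))

    def test_l1_norm_nonincreasing_in_lam(self, rng):
        X = rng.standard_normal((60, 6))
        Y = rng.standard_normal((60, 3))
        norms = [np.abs(fit_lasso_mm(X, Y, lam)).sum()
                 for lam in [0.0, 0.3, 1.0, 3.0, 10.0]]
        assert all(a >= b - 1e-8 for a, b in zip(norms, norms[1:]))


class TestCriteria:
    def test_gcv_values_and_errors(self):
        assert gcv_score(4.0, 10, 2) == pytest.approx(0.0625)
        assert gcv_score(0.0, 10, 2) == 0.0
        with pytest.raises(ValueError):
            gcv_score(1.0, 5, 5)

    def test_bic_values_and_monotonicity(self):
        assert bic_score(1.0, 120, 10) == pytest.approx((np.log(120) - 1) * 10 / 120)
        assert bic_score(2.0, 120, 0) == pytest.approx(np.log(2.0))
        assert bic_score(1.0, 120, 11) > bic_score(1.0, 120, 10)
        with pytest.raises(ValueError):
            bic_score(0.0, 120, 1)

    def test_singleton_grid(self, rng):
        windows = [[rng.standard_normal((30, 3))]]
        assert select_lambda(windows, np.array([2.5]), p=1) == 2.5

    def test_white_noise_prefers_strong_shrinkage(self, rng):
        windows = [[rng.standard_normal((40, 4)) for _ in range(3)] for _ in range(4)]
        grid = default_lambda_grid(10, 0.01, 100.0)
        lam = select_lambda(windows, grid, p=1)
        assert lam > np.median(grid)  # heavy shrinkage wins on pure noise

    def test_order_recovery(self, rng):
        # order-1 truth
        A1 = np.array([[0.5, 0.2], [0.0, 0.4]])
        w1 = [[ar_realization(A1, 60, rng) for _ in range(2)] for _ in range(5)]
        assert select_order(w1, lam=0.05) == 1
        # order-2 truth with strong lag-2 coefficients
        rng2 = np.random.default_rng(7)
        m = 2
        out = []
        for _ in range(5):
            segs = []
            for _ in range(2):
                y = np.zeros((260, m))
                y[:2] = rng2.standard_normal((2, m))
                for t in range(2, 260):
                    y[t] = 0.2 * y[t - 1] + np.array([[-0.6, 0.0], [0.3, -0.5]]) @ y[t - 2]
                    y[t] += rng2.standard_normal(m)
                segs.append(y[200:])
            out.append(segs)
        assert select_order(out, lam=0.05) == 2

    def test_white_noise_selects_order_one(self, rng):
        windows = [[rng.standard_normal((60, 3))] for _ in range(6)]
        assert select_order(windows, lam=0.05) == 1


class TestNetworkFeature:
    def test_mean_absolute_over_lags(self):
        m, p = 3, 2
        A = np.zeros((m * p, m))
        A[1, 0] = 0.2   # a_{0,1}(1)
        A[m + 1, 0] = -0.4  # a_{0,1}(2)
        f = network_from_coefficients(MVARModel(A, p, m, 0.0, np.ones(m)))
        assert f.W[0, 1] == pytest.approx(0.3)
        assert f.v.shape == (m * (m - 1),)

    def test_sign_is_dropped(self):
        A = np.array([[0.0, 0.0], [-0.3, 0.0]])
        f = network_from_coefficients(MVARModel(A, 1, 2, 0.0, np.ones(2)))
        assert f.W[0, 1] == pytest.approx(0.3)

    def test_zero_model(self):
        f = network_from_coefficients(MVARModel(np.zeros((4, 4)), 1, 4, 0.0, np.ones(4)))
        assert not f.W.any() and not f.v.any()

    def test_vectorization_is_row_major_without_diagonal(self):
        W_rows = np.arange(9, dtype=float).reshape(3, 3)
        A = W_rows.T.copy()  # p=1: A[j, i] = a_ij
        f = network_from_coefficients(MVARModel(A, 1, 3, 0.0, np.ones(3)))
        np.testing.assert_allclose(f.v, [1, 2, 3, 5, 6, 7])


class TestWindowing:
    @pytest.mark.parametrize(
        "n,width,d,group,exp_windows,exp_groups",
        [(1000, 40, 300, 3, 25, 100), (240, 12, 700, 10, 20, 70)],
    )
    def test_bookkeeping(self, n, width, d, group, exp_windows, exp_groups):
        spec = WindowSpec(width_samples=width, group_size=group)
        assert n // width == exp_windows
        assert d // group == exp_groups

    def test_window_networks_layout(self, small_tensor):
        spec = WindowSpec(width_samples=30, group_size=2)
        feats = window_networks(small_tensor, spec, lam=0.5, p=1)
        m = small_tensor.n_channels
        # 2 conditions x 3 groups x 4 windows
        assert feats.V.shape == (24, m * (m - 1))
        assert feats.n_windows == 4
        assert feats.groups_per_condition == {"a": 3, "b": 3}
        assert (feats.V >= 0).all()

    def test_group_size_one_is_per_trial(self, small_tensor):
        spec = WindowSpec(width_samples=60, group_size=1)
        feats = window_networks(small_tensor, spec, lam=0.5, p=1)
        assert feats.V.shape[0] == 12 * 2  # every trial, 2 windows each

    def test_too_few_trials_for_group_raises(self, small_tensor):
        with pytest.raises(ValueError, match="fewer than one group"):
            window_networks(small_tensor, WindowSpec(30, 7), lam=0.5, p=1)


class TestEstimatorInterface:
    def test_fit_sets_sklearn_style_attributes(self, rng):
        est = SparseMVAR(p=1, lam=0.3)
        segs = [rng.standard_normal((40, 4)) for _ in range(3)]
        est.fit(segs)
        assert est.coef_.shape == (4, 4)
        assert est.resid_var_.shape == (4,)
        assert est.converged_
        net = est.network_()
        assert net.W.shape == (4, 4)

    def test_get_params_roundtrip(self):
        est = SparseMVAR(p=2, lam=1.5)
        params = est.get_params()
        est2 = SparseMVAR(**params)
        assert est2.p == 2 and est2.lam == 1.5

    def test_sparse_recovery_beats_ols_on_sparse_truth(self, rng):
        m = 8
        A = np.zeros((m, m))
        idx = rng.choice(m * m, size=6, replace=False)
        A.flat[idx] = rng.uniform(0.1, 0.3, size=6)
        data = ar_realization(A, 40, rng)
        X, Y = build_lagged_regression([data], p=1)
        err_s = np.abs(fit_lasso_mm(X, Y, 1.0).T - A).sum()
        err_o = np.abs(fit_ols(X, Y).T - A).sum()
        assert err_s < err_o
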