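"""SVR engine: kernel, dual solution, prediction, serialization."""

import numpy as np
import pytest

from oracles import ols_fit, rbf_gram, svr_dual_qp
from qsrr.svr import SVRConfig, SVRModel, fit_svr, predict, rbf_kernel


class TestRBFKernel:
    def test_zero_distance(self):
        assert rbf_kernel([1.0, 2.0], [1.0, 2.0], 0.01) == 1.0

    def test_known_value(self):
        # gamma=0.01, squared distance 100 -> e^-1
        assert rbf_kernel([0.0], [10.0], 0.01) == pytest.approx(np.exp(-1))

    def test_gamma_one_unit_distance(self):
        assert rbf_kernel([0.0], [1.0], 1.0) == pytest.approx(np.exp(-1))

    def test_kernel_matrix_psd(self, rng):
        pts = rng.normal(size=(5, 3))
        K = np.array([[rbf_kernel(a, b, 0.7) for b in pts] for a in pts])
        np.testing.assert_allclose(K, K.T)
        assert np.min(np.linalg.eigvalsh(K)) >= -1e-10


class TestFit:
    def test_constant_response_flat_function(self, rng):
        X = rng.normal(size=(6, 2))
        y = np.full(6, 1.3)
        m = fit_svr(X, y, SVRConfig())
        np.testing.assert_allclose(predict(m, X), 1.3, atol=0.011)

    def test_1d_toy_matches_qp_dual(self):
        """Small-instance fit agrees with an independent SLSQP dual solve."""
        X = np.arange(4.0)[:, None]
        y = np.arange(4.0)
        cfg = SVRConfig(C=100.0, epsilon=0.01, gamma_kernel=0.5,
                        standardize=False)
        m = fit_svr(X, y, cfg)
        pred = predict(m, X)
        assert np.sqrt(np.mean((pred - y) ** 2)) < 0.05
        beta, bias = svr_dual_qp(rbf_gram(X, X, 0.5), y, 100.0, 0.01)
        np.testing.assert_allclose(pred, rbf_gram(X, X, 0.5) @ beta + bias,
                                   atol=1e-3)

    def test_duplicate_rows_equivalent(self, rng):
        """With no box constraint active the dual solution is unique in f, so
        duplicating training rows leaves the fitted function unchanged."""
        X = rng.normal(size=(6, 2))
        y = np.abs(rng.normal(size=6))
        cfg = SVRConfig(C=100.0, epsilon=0.05)
        m1 = fit_svr(X, y, cfg)
        assert np.all(np.abs(m1.dual_coef) < cfg.C - 1e-6)  # interior
        m2 = fit_svr(np.vstack([X, X]), np.concatenate([y, y]), cfg)
        q = rng.normal(size=(8, 2))
        np.testing.assert_allclose(predict(m1, q), predict(m2, q), atol=1e-3)

    def test_zero_variance_column_passthrough(self, rng):
        X = np.column_stack([rng.normal(size=6), np.full(6, 2.0)])
        m = fit_svr(X, np.abs(rng.normal(size=6)), SVRConfig())
        assert m.passthrough_columns == [1]


class TestPredict:
    def test_interpolating_fit_hits_training_values(self):
        X = np.linspace(0, 3, 4)[:, None]
        y = np.array([0.2, 0.9, 0.4, 1.1])
        cfg = SVRConfig(C=1000.0, epsilon=0.01, gamma_kernel=1.0)
        m = fit_svr(X, y, cfg)
        np.testing.assert_allclose(predict(m, X), y, atol=0.01 + 1e-6)

    def test_invariant_to_training_row_order(self, rng):
        X = rng.normal(size=(8, 3))
        y = np.abs(rng.normal(size=8))
        perm = rng.permutation(8)
        m1 = fit_svr(X, y, SVRConfig())
        m2 = fit_svr(X[perm], y[perm], SVRConfig())
        q = rng.normal(size=(5, 3))
        # solver tolerance is 1e-6; row order perturbs the solve path slightly
        np.testing.assert_allclose(predict(m1, q), predict(m2, q), atol=1e-4)

    def test_standardize_equivalence(self, rng):
        X = rng.normal(size=(10, 3)) * np.array([1.0, 10.0, 100.0])
        y = np.abs(rng.normal(size=10))
        gamma = 0.3
        m_std = fit_svr(X, y, SVRConfig(gamma_kernel=gamma, standardize=True))
        Z = (X - X.mean(0)) / X.std(0)
        m_pre = fit_svr(Z, y, SVRConfig(gamma_kernel=gamma, standardize=False))
        q = rng.normal(size=(6, 3)) * np.array([1.0, 10.0, 100.0])
        qz = (q - X.mean(0)) / X.std(0)
        np.testing.assert_allclose(predict(m_std, q), predict(m_pre, qz),
                                   atol=1e-8)

    def test_dimension_mismatch(self, rng):
        m = fit_svr(rng.normal(size=(5, 3)), np.abs(rng.normal(size=5)))
        with pytest.raises(ValueError, match="columns"):
            predict(m, rng.normal(size=(2, 4)))


class TestDualProperties:
    def test_box_and_equality_constraints(self, rng):
        for C in (0.5, 1.0, 10.0):
            X = rng.normal(size=(9, 2))
            y = np.abs(rng.normal(size=9))
            m = fit_svr(X, y, SVRConfig(C=C, epsilon=0.05))
            assert np.all(np.abs(m.dual_coef) <= C + 1e-8)
            assert abs(m.dual_coef.sum()) < 1e-8

    def test_support_count_non_increasing_in_epsilon(self, rng):
        X = rng.normal(size=(30, 2))
        y = np.sin(X[:, 0]) + 0.1 * rng.normal(size=30) + 1.5
        counts = [fit_svr(X, y, SVRConfig(epsilon=e)).n_support
                  for e in (0.0, 0.05, 0.1, 0.2, 0.4)]
        assert counts == sorted(counts, reverse=True)

    def test_linear_kernel_large_C_matches_ols(self, rng):
        """Degree-1 polynomial kernel, eps=0, huge C on noiseless linear data."""
        X = rng.normal(size=(12, 2))
        beta = np.array([1.5, -0.7])
        y = X @ beta + 0.2
        cfg = SVRConfig(C=1e4, epsilon=0.0, kernel="polynomial", degree=1,
                        gamma_kernel=1.0, coef0=0.0, standardize=False)
        m = fit_svr(X, y, cfg)
        coef, _ = ols_fit(X, y)
        q = rng.normal(size=(6, 2))
        ols_pred = np.column_stack([np.ones(6), q]) @ coef
        np.testing.assert_allclose(predict(m, q), ols_pred, atol=1e-3)


def test_json_roundtrip(tmp_path, rng):
    X = rng.normal(size=(7, 3))
    y = np.abs(rng.normal(size=7))
    m = fit_svr(X, y, SVRConfig(), descriptor_names=["a", "b", "c"])
    path = tmp_path / "model.json"
    m.to_json(path)
    back = SVRModel.from_json(path)
    q = rng.normal(size=(4, 3))
    np.testing.assert_allclose(predict(back, q), predict(m, q), atol=1e-12)
    assert back.descriptor_names == ["a", "b", "c"]
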