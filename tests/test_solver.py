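import numpy as np
import pytest

import graphscca as g
from graphscca.exceptions import NumericalError, ValidationError
from graphscca.solver import _solve_dense

from conftest import brute_force_goscar, make_correlated_data


class TestStandardize:
    def test_simple_column(self):
        data = g.PairedData(
            np.array([[1.0, 0.0], [2.0, 1.0], [3.0, -1.0]]),
            np.array([[1.0], [0.0], [2.0]]),
        )
        out = g.standardize(data)
        expected = np.array([-1.0, 0.0, 1.0]) / np.sqrt(2.0)
        assert np.allclose(out.X[:, 0], expected, atol=1e-12)
        assert out.standardized

    def test_columns_unit_norm_zero_mean(self, rng):
        data = g.standardize(
            g.PairedData(rng.standard_normal((20, 5)), rng.standard_normal((20, 6)))
        )
        for M in (data.X, data.Y):
            assert np.all(np.abs(M.mean(axis=0)) <= 1e-10)
            assert np.all(np.abs(np.linalg.norm(M, axis=0) - 1.0) <= 1e-10)

    def test_idempotent(self, rng):
        data = g.standardize(
            g.PairedData(rng.standard_normal((15, 4)), rng.standard_normal((15, 3)))
        )
        again = g.standardize(data)
        assert np.allclose(again.X, data.X, atol=1e-12)
        assert np.allclose(again.Y, data.Y, atol=1e-12)

    def test_constant_column_rejected(self):
        X = np.column_stack([np.full(5, 5.0), np.arange(5.0)])
        with pytest.raises(ValidationError, match="x1"):
            g.standardize(g.PairedData(X, np.arange(5.0).reshape(-1, 1)))

    def test_nan_rejected(self):
        X = np.ones((4, 2))
        X[0, 0] = np.nan
        with pytest.raises(ValidationError):
            g.PairedData(X, np.ones((4, 2)))


class TestConfig:
    def test_defaults_valid(self):
        cfg = g.SccaConfig()
        assert cfg.tau == 1e-5 and cfg.max_iter == 100 and cfg.zeta == 1e-10

    @pytest.mark.parametrize(
        "kwargs",
        [
            dict(tau=-1.0),
            dict(tau=0.0),
            dict(zeta=0.0),
            dict(gamma1=0.0),
            dict(lambda1=-0.5),
            dict(max_iter=0),
            dict(init="bogus"),
            dict(rescale="sometimes"),
        ],
    )
    def test_invalid_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            g.SccaConfig(**kwargs)


class TestObjective:
    def _graphs(self, data):
        return (g.FeatureGraph.complete(data.p), g.FeatureGraph.complete(data.q))

    def test_zero_loadings(self, small_data):
        cfg = g.SccaConfig()
        val = g.objective(
            np.zeros(small_data.p), np.zeros(small_data.q), small_data, cfg,
            self._graphs(small_data),
        )
        assert val == 0.0

    def test_sign_flip_invariance(self, small_data, rng):
        cfg = g.SccaConfig(lambda1=0.3, lambda2=0.2, beta1=0.4, beta2=0.1)
        u = rng.standard_normal(small_data.p)
        v = rng.standard_normal(small_data.q)
        gs = self._graphs(small_data)
        a = g.objective(u, v, small_data, cfg, gs)
        b = g.objective(-u, -v, small_data, cfg, gs)
        assert a == pytest.approx(b, rel=1e-12)

    def test_term_by_term_oracle(self, small_data, rng):
        # recompute every term independently, with the brute-force penalty
        cfg = g.SccaConfig(
            lambda1=0.7, lambda2=0.3, beta1=0.2, beta2=0.9, gamma1=1.3, gamma2=0.8
        )
        u = rng.standard_normal(small_data.p)
        v = rng.standard_normal(small_data.q)
        gu, gv = self._graphs(small_data)
        X, Y = small_data.X, small_data.Y
        expected = (
            -u @ X.T @ Y @ v
            + 0.7 * brute_force_goscar(u, gu.edges)
            + 0.3 * brute_force_goscar(v, gv.edges)
            + 0.5 * 0.2 * np.abs(u).sum()
            + 0.5 * 0.9 * np.abs(v).sum()
            + 0.5 * 1.3 * np.sum((X @ u) ** 2)
            + 0.5 * 0.8 * np.sum((Y @ v) ** 2)
        )
        val = g.objective(u, v, small_data, cfg, (gu, gv))
        assert val == pytest.approx(expected, rel=1e-10)

    def test_zeta_limit(self, small_data, rng):
        cfg = g.SccaConfig()
        u = rng.standard_normal(small_data.p)
        v = rng.standard_normal(small_data.q)
        gs = self._graphs(small_data)
        a = g.objective(u, v, small_data, cfg, gs, zeta=1e-14)
        b = g.objective(u, v, small_data, cfg, gs, zeta=1e-10)
        assert abs(a - b) / abs(a) < 1e-4


class TestUpdateLoading:
    def test_unpenalized_least_squares(self, rng):
        # lambda = beta = 0, gamma = 1, full-rank X: u = (X'X)^-1 X'Y v
        data = g.standardize(
            g.PairedData(rng.standard_normal((30, 8)), rng.standard_normal((30, 6)))
        )
        cfg = g.SccaConfig(lambda1=0.0, beta1=0.0, gamma1=1.0)
        v = rng.standard_normal(6)
        w = g.reweight(np.ones(data.p), g.FeatureGraph.complete(data.p), cfg.zeta)
        u = g.update_loading("u", data, v, w, cfg)
        expected = np.linalg.solve(data.X.T @ data.X, data.X.T @ data.Y @ v)
        assert np.max(np.abs(u - expected)) <= 1e-8

    def test_explicit_inverse_oracle(self, rng):
        # agreement with the closed-form matrix-inverse evaluation
        data = g.standardize(
            g.PairedData(rng.standard_normal((30, 10)), rng.standard_normal((30, 12)))
        )
        cfg = g.SccaConfig(lambda1=0.4, beta1=0.6, gamma1=1.2)
        v = rng.standard_normal(12)
        u_cur = rng.standard_normal(10)
        w = g.reweight(u_cur, g.FeatureGraph.complete(10), cfg.zeta)
        u = g.update_loading("u", data, v, w, cfg)
        A = (
            0.4 * (w.L + w.L_hat)
            + 0.6 * np.diag(w.lambda_diag)
            + 1.2 * data.X.T @ data.X
        )
        expected = np.linalg.inv(A) @ (data.X.T @ data.Y @ v)
        assert np.max(np.abs(u - expected)) <= 1e-8

    def test_rank_deficient_jitter_path(self, rng):
        # duplicated column makes gamma*X'X singular with no other penalty
        base = rng.standard_normal((20, 4))
        X = np.column_stack([base, base[:, 0]])
        X = X - X.mean(axis=0)
        X = X / np.linalg.norm(X, axis=0)
        data = g.PairedData(X, rng.standard_normal((20, 3)), standardized=True)
        cfg = g.SccaConfig(lambda1=0.0, beta1=0.0, gamma1=1.0)
        w = g.reweight(np.ones(5), g.FeatureGraph.empty(5), cfg.zeta)
        with pytest.warns(RuntimeWarning, match="jitter"):
            u = g.update_loading("u", data, rng.standard_normal(3), w, cfg)
        assert np.all(np.isfinite(u))

    def test_matfree_path_matches_dense(self, rng):
        data = g.standardize(
            g.PairedData(rng.standard_normal((40, 15)), rng.standard_normal((40, 10)))
        )
        cfg_dense = g.SccaConfig(lambda1=0.2, beta1=0.3)
        cfg_cg = cfg_dense.replace(dense_cap=5)  # force the matrix-free path
        v = rng.standard_normal(10)
        w = g.reweight(rng.standard_normal(15), g.FeatureGraph.complete(15), 1e-10)
        u_dense = g.update_loading("u", data, v, w, cfg_dense)
        u_cg = g.update_loading("u", data, v, w, cfg_cg)
        assert np.max(np.abs(u_dense - u_cg)) <= 1e-6

    def test_singular_system_raises(self):
        A = np.array([[1.0, 0.0], [0.0, -1e308]])
        with pytest.raises(NumericalError):
            _solve_dense(A, np.array([np.inf, np.nan]))


class TestFit:
    def test_monotone_decrease_final_rescale(self):
        # 20 random instances: the trace of the smoothed objective never rises
        for seed in range(20):
            rng = np.random.default_rng(seed)
            data = g.standardize(
                g.PairedData(rng.standard_normal((40, 30)), rng.standard_normal((40, 35)))
            )
            f = g.fit(data, None, g.SccaConfig(rescale="final"))
            tr = f.objective_trace
            assert np.all(tr[1:] <= tr[:-1] * (1 + 1e-8) + 1e-10), f"seed {seed}"

    def test_duplicate_datasets_perfect_correlation(self, rng):
        X = rng.standard_normal((30, 6))
        data = g.standardize(g.PairedData(X, X.copy()))
        cfg = g.SccaConfig(lambda1=1e-6, lambda2=1e-6, beta1=1e-6, beta2=1e-6)
        f = g.fit(data, None, cfg)
        assert f.train_correlation == pytest.approx(1.0, abs=1e-6)

    def test_requires_standardized(self, rng):
        data = g.PairedData(rng.standard_normal((20, 4)), rng.standard_normal((20, 5)))
        with pytest.raises(ValidationError):
            g.fit(data, None, g.SccaConfig())

    def test_loadings_satisfy_projection_constraints(self):
        data = make_correlated_data(3)
        f = g.fit(data, None, g.SccaConfig())
        assert np.linalg.norm(data.X @ f.u) == pytest.approx(1.0, abs=1e-10)
        assert np.linalg.norm(data.Y @ f.v) == pytest.approx(1.0, abs=1e-10)

    def test_sign_pair_symmetry(self):
        import warnings

        data = make_correlated_data(7)
        cfg = g.SccaConfig(max_iter=30)
        u0 = np.ones(data.p) / np.linalg.norm(data.X @ np.ones(data.p))
        v0 = np.ones(data.q) / np.linalg.norm(data.Y @ np.ones(data.q))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f1 = g.fit(data, None, cfg, init_loadings=(u0, v0))
            f2 = g.fit(data, None, cfg, init_loadings=(-u0, -v0))
        assert np.allclose(f1.u, -f2.u, atol=1e-8)
        assert np.allclose(f1.v, -f2.v, atol=1e-8)
        assert np.allclose(f1.objective_trace, f2.objective_trace, atol=1e-10)

    def test_lasso_limit_no_graph_contribution(self):
        import warnings

        data = make_correlated_data(11)
        cfg = g.SccaConfig(lambda1=0.0, lambda2=0.0, beta1=0.1, beta2=0.1)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f = g.fit(data, None, cfg)
        gs = (g.FeatureGraph.complete(data.p), g.FeatureGraph.complete(data.q))
        with_term = g.objective(f.u, f.v, data, cfg, gs)
        without = g.objective(
            f.u, f.v, data, cfg.replace(lambda1=1.0, lambda2=1.0), gs
        ) - (
            g.goscar_norm(f.u, gs[0]) + g.goscar_norm(f.v, gs[1])
        )
        assert with_term == pytest.approx(without, rel=1e-10)

    def test_kkt_residuals_at_convergence(self):
        sc = g.make_scenario("1")
        cfg = g.tuned_config("1")
        for seed in range(3):
            data = g.standardize(g.generate(sc, seed=seed).data)
            f = g.fit(data, None, cfg)
            assert f.converged
            ru, rv = g.kkt_residuals(f, data)
            assert max(np.abs(ru).max(), np.abs(rv).max()) <= 10 * cfg.tau

    def test_nonconvergence_warns(self):
        data = make_correlated_data(5)
        cfg = g.SccaConfig(max_iter=1, tau=1e-12)
        with pytest.warns(RuntimeWarning, match="did not converge"):
            f = g.fit(data, None, cfg)
        assert not f.converged

    def test_reproducible_random_init(self):
        data = make_correlated_data(9)
        cfg = g.SccaConfig(init="random", seed=42, max_iter=20)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            f1 = g.fit(data, None, cfg)
            f2 = g.fit(data, None, cfg)
        assert np.array_equal(f1.u, f2.u)
        assert np.array_equal(f1.v, f2.v)


class TestCanonicalCorrelation:
    def test_zero_loading_is_nan(self, small_data):
        val = g.canonical_correlation(
            np.zeros(small_data.p), np.ones(small_data.q), small_data.X, small_data.Y
        )
        assert np.isnan(val)

    def test_self_correlation(self, small_data, rng):
        u = rng.standard_normal(small_data.p)
        assert g.canonical_correlation(
            u, u, small_data.X, small_data.X
        ) == pytest.approx(1.0)

    def test_textbook_pearson_oracle(self, small_data, rng):
        u = rng.standard_normal(small_data.p)
        v = rng.standard_normal(small_data.q)
        a = small_data.X @ u
        b = small_data.Y @ v
        expected = (
            np.sum((a - a.mean()) * (b - b.mean()))
            / np.sqrt(np.sum((a - a.mean()) ** 2) * np.sum((b - b.mean()) ** 2))
        )
        val = g.canonical_correlation(u, v, small_data.X, small_data.Y)
        assert val == pytest.approx(expected, abs=1e-12)

    def test_constant_projection_is_nan(self):
        X = np.ones((5, 2))
        Y = np.arange(10.0).reshape(5, 2)
        assert np.isnan(g.canonical_correlation(np.ones(2), np.ones(2), X, Y))

    def test_dimension_mismatch(self, small_data):
        with pytest.raises(ValidationError):
            g.canonical_correlation(
                np.ones(3), np.ones(small_data.q), small_data.X, small_data.Y
            )
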