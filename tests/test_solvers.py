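import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gxnet import (
    DegenerateGridError,
    ENConfig,
    OMPConfig,
    en_alpha_grid,
    en_fit,
    en_select,
    omp_fit,
    omp_select_d0,
)
from gxnet.solvers import kfold_indices, standardize_columns


def naive_greedy_omp(X, y, d0):
    """Independent oracle: greedy max-|correlation| selection with a full
    least-squares re-solve from scratch at every step."""
    n, p = X.shape
    support = []
    coef = np.zeros(p)
    resid = y.copy()
    for _ in range(d0):
        corr = np.abs(X.T @ resid)
        corr[support] = -np.inf
        j = int(np.argmax(corr))
        support.append(j)
        sol, *_ = np.linalg.lstsq(X[:, support], y, rcond=None)
        coef = np.zeros(p)
        coef[support] = sol
        resid = y - X[:, support] @ sol
        if np.linalg.norm(resid) < 1e-12:
            break
    return coef, set(support[: np.count_nonzero(coef) or len(support)])


def _standardized(rng, n, p):
    X = rng.normal(size=(n, p))
    Xs, *_ = standardize_columns(X)
    return Xs


class TestOmpFit:
    def test_zero_budget_gives_empty_model(self, rng):
        Xs = _standardized(rng, 15, 4)
        fit = omp_fit(Xs, rng.normal(size=15), 0)
        assert fit.support == set()
        assert np.all(fit.coefficients == 0)

    def test_exact_single_column_match(self, rng):
        Xs = _standardized(rng, 20, 5)
        y = Xs[:, 3].copy()
        fit = omp_fit(Xs, y, 1)
        assert fit.support == {3}
        assert fit.coefficients[3] == pytest.approx(1.0, abs=1e-10)

    def test_matches_naive_greedy_oracle(self, rng):
        for _ in range(50):
            n, p = 20, 6
            Xs = _standardized(rng, n, p)
            y = rng.normal(size=n)
            y -= y.mean()
            for d0 in (1, 2, 3):
                fit = omp_fit(Xs, y, d0)
                coef, support = naive_greedy_omp(Xs, y, d0)
                assert fit.support == set(np.flatnonzero(coef))
                np.testing.assert_allclose(fit.coefficients, coef, atol=1e-8)

    def test_residual_norm_non_increasing(self, rng):
        Xs = _standardized(rng, 30, 8)
        y = rng.normal(size=30)
        y -= y.mean()
        norms = []
        for d0 in range(7):
            fit = omp_fit(Xs, y, d0)
            norms.append(np.linalg.norm(y - Xs @ fit.coefficients))
        assert all(b <= a + 1e-10 for a, b in zip(norms, norms[1:]))

    def test_negative_budget_rejected(self, rng):
        with pytest.raises(ValueError):
            omp_fit(_standardized(rng, 10, 3), np.zeros(10), -1)


class TestOmpSelect:
    def test_d0max_fraction_rule(self):
        # 195 candidate regulators at delta=0.5 caps the budget at 97
        cfg = OMPConfig(delta=0.5)
        from gxnet.solvers import omp_d0max

        rng = np.random.default_rng(0)
        Xs = _standardized(rng, 400, 195)
        assert omp_d0max(Xs, cfg) == 97

    def test_rank_caps_budget(self, rng):
        X = rng.normal(size=(30, 4))
        X = np.hstack([X, X @ rng.normal(size=(4, 4))])  # rank 4, p = 8
        Xs, *_ = standardize_columns(X)
        from gxnet.solvers import omp_d0max

        assert omp_d0max(Xs, OMPConfig(delta=1.0)) == 4

    def test_pure_noise_prefers_empty_model(self):
        # Under pure noise the argmax-of-mean-validation-R2 rule (the same
        # rule used for real selections) should usually return the empty
        # model, and never one that appears to generalize.  The majority
        # rate below was frozen from this exact seeded simulation.
        hits = 0
        n_rep = 60
        for s in range(n_rep):
            rng = np.random.default_rng(s)
            X = rng.normal(size=(40, 6))
            y = rng.normal(size=40)
            best_d0, fit = omp_select_d0(X, y, OMPConfig(delta=1.0, k_inner=5), seed=s)
            hits += best_d0 == 0
            assert np.nanmax(fit.cv_mean_r2) <= 0.2
        assert hits / n_rep >= 0.7

    def test_planted_support_recovered(self):
        for s in range(5):
            rng = np.random.default_rng(100 + s)
            X = rng.normal(size=(80, 8))
            y = 1.5 * X[:, 2] - 2.0 * X[:, 5] + rng.normal(scale=0.01, size=80)
            best_d0, fit = omp_select_d0(X, y, OMPConfig(delta=0.5), seed=s)
            assert best_d0 == 2
            assert fit.support == {2, 5}

    def test_original_scale_prediction(self, rng):
        X = rng.normal(loc=5.0, scale=3.0, size=(60, 5))
        y = 2.0 * X[:, 1] + 7.0 + rng.normal(scale=0.01, size=60)
        _, fit = omp_select_d0(X, y, OMPConfig(delta=0.5), seed=0)
        pred = fit.predict(X)
        assert np.corrcoef(pred, y)[0, 1] > 0.999
        assert fit.coefficients[1] == pytest.approx(2.0, abs=0.01)
        assert fit.intercept == pytest.approx(7.0, abs=0.2)

    def test_too_few_rows_rejected(self, rng):
        with pytest.raises(ValueError):
            omp_select_d0(rng.normal(size=(3, 4)), np.zeros(3), OMPConfig(k_inner=5))


class TestAlphaGrid:
    def test_hand_computed_cross_product(self):
        # frozen 4x2 standardized toy: cross-product computed by hand below
        x1 = np.array([1.0, -1.0, 1.0, -1.0])
        x2 = np.array([1.0, 1.0, -1.0, -1.0])
        x3 = (x1 + x2) / np.sqrt(2.0)  # correlated with both
        X = np.column_stack([x1, x3])
        # x1^T x3 = (x1.x1 + x1.x2)/sqrt2 = 4/sqrt2 = 2*sqrt2
        expected_amax = (4.0 / np.sqrt(2.0)) / (4.0 * 1.0)
        grid = en_alpha_grid(X, rho=1.0, K_alpha=4, epsilon=0.25)
        assert grid[0] == pytest.approx(expected_amax, rel=1e-12)
        assert grid[-1] == pytest.approx(0.25 * expected_amax, rel=1e-12)
        assert np.all(np.diff(grid) < 0)

    def test_epsilon_default_one_over_k(self):
        cfg = ENConfig(K_alpha=3)
        assert cfg.epsilon == pytest.approx(1 / 3)
        rng = np.random.default_rng(0)
        Xs = _standardized(rng, 30, 5)
        grid = en_alpha_grid(Xs, 1.0, 3, 1 / 3)
        assert len(grid) == 3
        assert grid[-1] == pytest.approx(grid[0] / 3)

    def test_grid_scales_inversely_with_rho(self, rng):
        Xs = _standardized(rng, 20, 6)
        g1 = en_alpha_grid(Xs, 1.0, 5, 0.2)
        g2 = en_alpha_grid(Xs, 0.5, 5, 0.2)
        np.testing.assert_allclose(g2, 2 * g1, rtol=1e-12)

    def test_orthogonal_design_raises(self):
        X = np.sqrt(4) * np.linalg.qr(np.random.default_rng(0).normal(size=(4, 2)))[0]
        with pytest.raises(DegenerateGridError):
            en_alpha_grid(X, 1.0, 3, 0.1)


class TestEnFit:
    def test_null_at_alpha_max(self, rng):
        Xs = _standardized(rng, 40, 10)
        y = Xs[:, 0].copy()
        grid = en_alpha_grid(Xs, 0.9, 5, 0.2)
        fit = en_fit(Xs[:, 1:], y, grid[0], 0.9, seed=0)
        assert np.all(fit.coefficients == 0)

    def test_ridge_closed_form_single_feature(self, rng):
        n = 50
        x = rng.normal(size=n)
        x = (x - x.mean()) / x.std()
        y = 0.8 * x + rng.normal(scale=0.1, size=n)
        y -= y.mean()
        alpha = 0.3
        fit = en_fit(x[:, None], y, alpha, rho=0.0, seed=0, tol=1e-10)
        expected = (x @ y) / (x @ x + n * alpha)
        assert fit.coefficients[0] == pytest.approx(expected, abs=1e-6)

    def test_soft_threshold_orthonormal_design(self, rng):
        n, p = 32, 4
        Q, _ = np.linalg.qr(rng.normal(size=(n, p)))
        X = Q * np.sqrt(n)  # X^T X = n I
        y = X @ np.array([1.0, -0.5, 0.05, 0.0]) + rng.normal(scale=0.01, size=n)
        y -= y.mean()
        alpha = 0.2
        fit = en_fit(X, y, alpha, rho=1.0, seed=0, tol=1e-10, max_iter=50_000)
        z = X.T @ y / n
        expected = np.sign(z) * np.maximum(np.abs(z) - alpha, 0.0)
        np.testing.assert_allclose(fit.coefficients, expected, atol=1e-6)

    def test_seed_reproducibility(self, rng):
        Xs = _standardized(rng, 30, 8)
        y = rng.normal(size=30)
        y -= y.mean()
        f1 = en_fit(Xs, y, 0.05, 0.9, seed=7)
        f2 = en_fit(Xs, y, 0.05, 0.9, seed=7)
        np.testing.assert_array_equal(f1.coefficients, f2.coefficients)
        f3 = en_fit(Xs, y, 0.05, 0.9, seed=8, tol=1e-9)
        # different coordinate orders agree in objective value
        def obj(c):
            return (np.sum((y - Xs @ c) ** 2) / (2 * len(y))
                    + 0.05 * 0.9 * np.abs(c).sum() + 0.05 * 0.1 / 2 * c @ c)
        assert obj(f3.coefficients) == pytest.approx(obj(f1.coefficients), abs=1e-6)

    def test_kkt_conditions_hold(self, rng):
        n, p = 60, 10
        Xs = _standardized(rng, n, p)
        y = Xs @ rng.normal(size=p) + rng.normal(size=n)
        y -= y.mean()
        alpha, rho = 0.1, 0.9
        fit = en_fit(Xs, y, alpha, rho, seed=0, tol=1e-12, max_iter=100_000)
        c = fit.coefficients
        grad = Xs.T @ (y - Xs @ c) / n - alpha * (1 - rho) * c
        for j in range(p):
            if c[j] != 0:
                assert grad[j] == pytest.approx(alpha * rho * np.sign(c[j]), abs=1e-5)
            else:
                assert abs(grad[j]) <= alpha * rho + 1e-5


class TestEnSelect:
    def test_planted_two_feature_model(self, rng):
        X = rng.normal(size=(100, 10))
        y = 1.2 * X[:, 3] - 0.7 * X[:, 6]
        alpha, rho, fit = en_select(X, y, ENConfig(K_alpha=20, seed=0), seed=0)
        assert {3, 6} <= fit.support
        pred = fit.predict(X)
        from gxnet import r2_score

        assert r2_score(y, pred) > 0.99

    def test_pure_noise_low_r2(self):
        ok = 0
        n_rep = 25
        for s in range(n_rep):
            rng = np.random.default_rng(500 + s)
            X = rng.normal(size=(50, 8))
            y = rng.normal(size=50)
            _, _, fit = en_select(X, y, ENConfig(K_alpha=4), seed=s)
            best = np.nanmax(fit.cv_mean_r2)
            ok += best <= 0.05
        assert ok / n_rep >= 0.9

    def test_degenerate_grid_returns_null_model(self, rng):
        X = rng.normal(size=(30, 6))
        y = rng.normal(size=30)
        alpha, rho, fit = en_select(X, y, ENConfig(rho_grid=(1.0,), K_alpha=1), seed=0)
        assert rho == 1.0
        assert np.all(fit.coefficients == 0)


@settings(max_examples=20, deadline=None, derandomize=True)
@given(st.integers(5, 60), st.integers(2, 7), st.integers(0, 1000))
def test_kfold_partitions_rows_exactly_once(n, k, seed):
    if n < k:
        return
    rng = np.random.default_rng(seed)
    folds = kfold_indices(n, k, rng)
    allidx = np.concatenate(folds)
    assert sorted(allidx.tolist()) == list(range(n))
    sizes = [f.size for f in folds]
    assert max(sizes) - min(sizes) <= 1
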