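"""Constrained sparse linear solvers: OMP with an l0 budget and ElasticNet
with a pathwise alpha grid, each with an inner cross-validation selector.

Both solvers operate on standardized designs: the low-level ``omp_fit`` /
``en_fit`` primitives assume z-scored feature columns and a centered target
and return coefficients on that standardized scale, while the selectors
(``omp_select_d0``, ``en_select``) accept raw data, standardize per training
fold (statistics from training rows only), and report the final refit on the
original feature scale with the intercept implied by centering.

The ElasticNet objective is

    ||y - X c||^2 / (2 D) + alpha * rho * ||c||_1
                          + alpha * (1 - rho) / 2 * ||c||^2

minimized by coordinate descent with a seeded random coordinate order.  The
alpha grid is anchored at the pairwise cross-product bound

    alpha_max = max_{i != j} |X_i^T X_j| / (D * rho)

for which the coefficient vector is null on standardized self-expressive
data, and descends on a log scale to alpha_min = eps * alpha_max.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import ElasticNet, OrthogonalMatchingPursuit


class DegenerateGridError(ValueError):
    """Raised when all pairwise cross-products vanish (perfectly orthogonal
    design); callers may fall back to an alpha_max derived from |X^T y|."""


DEFAULT_RHO_GRID = (0.8, 0.9, 0.99, 1.0)


@dataclass
class OMPConfig:
    """Settings for the l0-budget solver.

    ``delta`` caps the budget at a fraction of the candidate count; the
    admissible budget range is 0..d0max with
    d0max = min(floor(delta * p), numerical_rank(X)) unless overridden.
    """

    delta: float = 0.5
    d0max_override: int | None = None
    k_inner: int = 5

    def __post_init__(self) -> None:
        if not 0 < self.delta <= 1:
            raise ValueError("delta must lie in (0, 1]")
        if self.k_inner < 2:
            raise ValueError("k_inner must be >= 2")
        if self.d0max_override is not None and self.d0max_override < 1:
            raise ValueError("d0max_override must be positive")


@dataclass
class ENConfig:
    """Settings for the ElasticNet solver.

    ``epsilon`` defaults to 1/K_alpha, shrinking the explored alpha range
    as fewer grid points are requested.
    """

    rho_grid: tuple[float, ...] = DEFAULT_RHO_GRID
    K_alpha: int = 10
    epsilon: float | None = None
    k_inner: int = 5
    max_iter: int = 10_000
    tol: float = 1e-6
    seed: int = 0

    def __post_init__(self) -> None:
        if self.K_alpha < 1:
            raise ValueError("K_alpha must be positive")
        if self.epsilon is None:
            self.epsilon = 1.0 / self.K_alpha
        if not 0 < self.epsilon < 1 and self.K_alpha > 1:
            raise ValueError("epsilon must lie in (0, 1)")
        for r in self.rho_grid:
            if not 0 < r <= 1:
                raise ValueError("rho values must lie in (0, 1]")


@dataclass
class FitResult:
    """A fitted sparse linear model for one target."""

    coefficients: np.ndarray
    intercept: float
    support: set[int]
    selected_hyperparams: dict
    cv_mean_r2: np.ndarray | None = field(default=None, repr=False)

    def predict(self, X: np.ndarray) -> np.ndarray:
        return X @ self.coefficients + self.intercept


# ---------------------------------------------------------------------------
# standardization and CV plumbing
# ---------------------------------------------------------------------------


def standardize_columns(X: np.ndarray):
    """Z-score columns (population std); constant columns are flagged for
    exclusion from the candidate set and left at zero."""
    X = np.asarray(X, dtype=float)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    keep = sd > 0
    Xs = np.zeros_like(X)
    Xs[:, keep] = (X[:, keep] - mu[keep]) / sd[keep]
    return Xs, mu, sd, keep


def kfold_indices(n: int, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Rows shuffled once, then split into k near-equal contiguous blocks;
    remainder rows go to the first folds."""
    if n < k:
        raise ValueError(f"cannot split {n} rows into {k} folds")
    perm = rng.permutation(n)
    return [np.sort(chunk) for chunk in np.array_split(perm, k)]


def _unstandardize(coef_std, y_mean, mu, sd, keep):
    p = keep.shape[0]
    coef = np.zeros(p)
    coef[keep] = coef_std[keep] / sd[keep]
    intercept = float(y_mean - coef @ mu)
    return coef, intercept


def validation_r2(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0:
        return np.nan
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


# ---------------------------------------------------------------------------
# OMP
# ---------------------------------------------------------------------------


def omp_fit(X: np.ndarray, y: np.ndarray, d0: int) -> FitResult:
    """Greedy forward selection with orthogonal re-projection.

    At each step the feature with the largest |correlation with the current
    residual| is added, all selected coefficients are refit by least squares
    and the residual recomputed; exactly min(d0, steps to a zero residual)
    features end up selected.  Expects standardized columns and a centered
    target; coefficients are on the standardized scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if d0 < 0:
        raise ValueError("d0 must be non-negative")
    p = X.shape[1]
    if d0 == 0 or p == 0:
        return FitResult(np.zeros(p), 0.0, set(), {"d0": d0})
    d0 = min(d0, p)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        est = OrthogonalMatchingPursuit(n_nonzero_coefs=d0, fit_intercept=False)
        est.fit(X, y)
    coef = np.asarray(est.coef_, dtype=float)
    support = set(int(i) for i in np.flatnonzero(coef))
    return FitResult(coef, 0.0, support, {"d0": d0})


def numerical_rank(X: np.ndarray) -> int:
    """Rank by singular values above max(n, p) * eps * sigma_max."""
    if X.size == 0:
        return 0
    return int(np.linalg.matrix_rank(X))


def omp_d0max(X_std: np.ndarray, cfg: OMPConfig) -> int:
    if cfg.d0max_override is not None:
        return min(cfg.d0max_override, X_std.shape[1])
    p = X_std.shape[1]
    return min(int(np.floor(cfg.delta * p)), numerical_rank(X_std))


def omp_select_d0(
    X: np.ndarray, y: np.ndarray, cfg: OMPConfig, seed: int = 0
) -> tuple[int, FitResult]:
    """Pick the l0 budget by inner cross-validation.

    Candidates are d0 = 0..d0max; for each, the mean validation R^2 over
    ``k_inner`` folds is computed and the best budget selected, ties broken
    toward the smallest d0 (parsimony).  The returned fit is refit on all
    provided rows and reported on the original feature scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    folds = kfold_indices(n, cfg.k_inner, rng)

    Xs_all, mu_all, sd_all, keep_all = standardize_columns(X)
    d0max = omp_d0max(Xs_all[:, keep_all], cfg)

    scores = np.full((cfg.k_inner, d0max + 1), np.nan)
    for fi, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        Xtr_s, mu, sd, keep = standardize_columns(X[train_idx])
        ytr = y[train_idx]
        ytr_c = ytr - ytr.mean()
        Xval_s = np.zeros((val_idx.size, p))
        Xval_s[:, keep] = (X[val_idx][:, keep] - mu[keep]) / sd[keep]
        cap = min(d0max, int(keep.sum()))
        for d0 in range(d0max + 1):
            fit = omp_fit(Xtr_s[:, keep], ytr_c, min(d0, cap))
            coef = np.zeros(p)
            coef[keep] = fit.coefficients
            pred = ytr.mean() + Xval_s @ coef
            scores[fi, d0] = validation_r2(y[val_idx], pred)

    mean_scores = np.nanmean(scores, axis=0) if not np.all(np.isnan(scores)) else np.zeros(d0max + 1)
    best_d0 = int(np.nanargmax(mean_scores)) if np.any(np.isfinite(mean_scores)) else 0

    fit_std = omp_fit(Xs_all[:, keep_all], y - y.mean(), best_d0)
    coef_std = np.zeros(p)
    coef_std[keep_all] = fit_std.coefficients
    coef, intercept = _unstandardize(coef_std, y.mean(), mu_all, sd_all, keep_all)
    result = FitResult(
        coef,
        intercept,
        set(int(i) for i in np.flatnonzero(coef)),
        {"d0": best_d0},
        cv_mean_r2=mean_scores,
    )
    return best_d0, result


# ---------------------------------------------------------------------------
# ElasticNet
# ---------------------------------------------------------------------------


def en_alpha_grid(
    X_learn: np.ndarray, rho: float, K_alpha: int, epsilon: float
) -> np.ndarray:
    """Log-spaced decreasing alpha sequence anchored at the pairwise bound
    alpha_max = max_{i!=j} |X_i^T X_j| / (D * rho)."""
    if rho <= 0:
        raise ValueError("rho must be positive for the alpha grid")
    X_learn = np.asarray(X_learn, dtype=float)
    D = X_learn.shape[0]
    G = X_learn.T @ X_learn
    np.fill_diagonal(G, 0.0)
    m = float(np.max(np.abs(G))) if G.size else 0.0
    if m <= D * 1e-12:
        raise DegenerateGridError(
            "all pairwise cross-products are zero (orthogonal design); "
            "fall back to alpha_max = max |X^T y| / (D * rho)"
        )
    alpha_max = m / (D * rho)
    if K_alpha == 1:
        return np.array([alpha_max])
    return np.geomspace(alpha_max, epsilon * alpha_max, K_alpha)


def en_fit(
    X: np.ndarray,
    y: np.ndarray,
    alpha: float,
    rho: float,
    seed: int = 0,
    max_iter: int = 10_000,
    tol: float = 1e-6,
) -> FitResult:
    """Coordinate descent with a seeded random coordinate order.

    Expects a standardized design and centered target; deterministic given
    the seed.  On non-convergence a warning is emitted and the current
    iterate returned.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if not 0 <= rho <= 1:
        raise ValueError("rho must lie in [0, 1]")
    est = ElasticNet(
        alpha=alpha,
        l1_ratio=rho,
        fit_intercept=False,
        selection="random",
        random_state=int(seed) % (2**32),
        max_iter=max_iter,
        tol=tol,
    )
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        warnings.simplefilter("ignore", UserWarning)
        est.fit(X, y)
    for w in caught:
        if issubclass(w.category, ConvergenceWarning):
            warnings.warn(
                f"coordinate descent did not converge within {max_iter} "
                f"iterations: {w.message}",
                ConvergenceWarning,
                stacklevel=2,
            )
    coef = np.asarray(est.coef_, dtype=float)
    return FitResult(
        coef,
        0.0,
        set(int(i) for i in np.flatnonzero(coef)),
        {"alpha": alpha, "rho": rho},
    )


def en_select(
    X: np.ndarray, y: np.ndarray, cfg: ENConfig, seed: int = 0
) -> tuple[float, float, FitResult]:
    """Select (alpha, rho) on a grid by inner cross-validation.

    The alpha grid is recomputed per rho from the standardized candidate
    columns augmented with the standardized target (so the null-vector
    property at alpha_max holds for every gene).  The best pair maximizes
    mean validation R^2; ties prefer larger rho then larger alpha (the
    sparser model).  The final fit is refit on all rows and reported on the
    original feature scale.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    n, p = X.shape
    rng = np.random.default_rng(seed)
    folds = kfold_indices(n, cfg.k_inner, rng)

    Xs_all, mu_all, sd_all, keep_all = standardize_columns(X)
    y_sd = y.std()
    if y_sd > 0:
        grid_basis = np.column_stack([Xs_all[:, keep_all], (y - y.mean()) / y_sd])
    else:
        grid_basis = Xs_all[:, keep_all]

    rho_grid = list(cfg.rho_grid)
    alpha_grids = [en_alpha_grid(grid_basis, rho, cfg.K_alpha, cfg.epsilon) for rho in rho_grid]

    scores = np.full((len(rho_grid), cfg.K_alpha, cfg.k_inner), np.nan)
    for fi, val_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(n), val_idx)
        Xtr_s, mu, sd, keep = standardize_columns(X[train_idx])
        ytr = y[train_idx]
        ytr_c = ytr - ytr.mean()
        Xval_s = np.zeros((val_idx.size, p))
        Xval_s[:, keep] = (X[val_idx][:, keep] - mu[keep]) / sd[keep]
        for ri, rho in enumerate(rho_grid):
            est = ElasticNet(
                l1_ratio=rho,
                fit_intercept=False,
                selection="random",
                random_state=int(seed + fi) % (2**32),
                max_iter=cfg.max_iter,
                tol=cfg.tol,
                warm_start=True,
            )
            for ai, alpha in enumerate(alpha_grids[ri]):
                est.set_params(alpha=alpha)
                with warnings.catch_warnings():
                    warnings.simplefilter("ignore", ConvergenceWarning)
                    est.fit(Xtr_s[:, keep], ytr_c)
                coef = np.zeros(p)
                coef[keep] = est.coef_
                pred = ytr.mean() + Xval_s @ coef
                scores[ri, ai, fi] = validation_r2(y[val_idx], pred)

    mean_scores = np.nanmean(scores, axis=2)
    if not np.any(np.isfinite(mean_scores)):
        best_ri, best_ai = len(rho_grid) - 1, 0
    else:
        best = np.nanmax(mean_scores)
        # ties toward larger rho, then larger alpha (earlier in the grid)
        candidates = [
            (ri, ai)
            for ri in range(len(rho_grid))
            for ai in range(cfg.K_alpha)
            if np.isfinite(mean_scores[ri, ai]) and mean_scores[ri, ai] == best
        ]
        best_ri, best_ai = max(candidates, key=lambda t: (rho_grid[t[0]], -t[1]))
    best_rho = rho_grid[best_ri]
    best_alpha = float(alpha_grids[best_ri][best_ai])

    fit_std = en_fit(
        Xs_all[:, keep_all],
        y - y.mean(),
        best_alpha,
        best_rho,
        seed=seed,
        max_iter=cfg.max_iter,
        tol=cfg.tol,
    )
    coef_std = np.zeros(p)
    coef_std[keep_all] = fit_std.coefficients
    coef, intercept = _unstandardize(coef_std, y.mean(), mu_all, sd_all, keep_all)
    result = FitResult(
        coef,
        intercept,
        set(int(i) for i in np.flatnonzero(coef)),
        {"alpha": best_alpha, "rho": best_rho},
        cv_mean_r2=mean_scores,
    )
    return best_alpha, best_rho, result
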