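"""Per-gene nested cross-validation orchestration.

For every gene g the expression column X[:, g] is regressed on the
regulator columns (excluding g itself), with an inner cross-validation
selecting the solver hyperparameters and an outer cross-validation
monitoring generalization on conditions never used for selection.  The
assembled coefficient matrix C (regulators x genes) is the gene
self-expressive network: C[psi, g] != 0 reads "regulator psi participates
in the model of gene g".  Structural constraints: the diagonal over
regulators is zero (no self-loops) and non-regulator rows are zero by
construction.
"""

from __future__ import annotations

import time
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix, RegulatorSet
from .solvers import (
    ENConfig,
    OMPConfig,
    en_select,
    kfold_indices,
    omp_select_d0,
)


def r2_score(y_true: np.ndarray, y_pred: np.ndarray) -> float:
    """Coefficient of determination 1 - SS_res / SS_tot.

    1 for a perfect prediction, 0 when the model is equivalent to a
    constant predicting the mean of ``y_true`` on the evaluated fold, and
    arbitrarily negative for unadapted models.  Undefined (NaN) when
    ``y_true`` is constant.
    """
    y_true = np.asarray(y_true, dtype=float)
    y_pred = np.asarray(y_pred, dtype=float)
    if y_true.shape != y_pred.shape or y_true.ndim != 1:
        raise ValueError("y_true and y_pred must be 1-D vectors of equal length")
    if y_true.size < 2:
        raise ValueError("need at least two observations")
    ss_tot = float(np.sum((y_true - y_true.mean()) ** 2))
    if ss_tot == 0.0:
        return float("nan")
    return 1.0 - float(np.sum((y_true - y_pred) ** 2)) / ss_tot


@dataclass
class GeneCVReport:
    """Outer-fold diagnostics for one gene's regression model."""

    gene_id: str
    outer_fold_r2: list[float]
    outer_hyperparams: list[dict]
    outer_runtimes: list[float]
    mean_r2: float
    selected_hyperparams: dict
    fit_runtime_seconds: float
    flags: list[str] = field(default_factory=list)


@dataclass
class GXNModel:
    """Sparse coefficient matrix C plus per-gene CV diagnostics.

    ``C`` has one row per regulator and one column per gene;
    C[psi, g] is the coefficient of regulator psi in gene g's model.
    """

    C: np.ndarray
    regulator_ids: list[str]
    gene_ids: list[str]
    per_gene: dict[str, GeneCVReport]
    method_tag: str
    k_inner: int
    k_outer: int
    seed: int

    def __post_init__(self) -> None:
        self._reg_index = {r: i for i, r in enumerate(self.regulator_ids)}
        self._gene_index = {g: i for i, g in enumerate(self.gene_ids)}

    def validate(self) -> None:
        for r in self.regulator_ids:
            if r in self._gene_index and self.C[self._reg_index[r], self._gene_index[r]] != 0:
                raise ValueError(f"self-loop coefficient for regulator {r}")
        if set(self.per_gene) != set(self.gene_ids):
            raise ValueError("per_gene diagnostics must cover every gene")

    def coefficient(self, regulator: str, gene: str) -> float:
        return float(self.C[self._reg_index[regulator], self._gene_index[gene]])

    def edges(self):
        """Yield (regulator, gene, coefficient) for every nonzero entry."""
        rows, cols = np.nonzero(self.C)
        for i, j in zip(rows, cols):
            yield (self.regulator_ids[i], self.gene_ids[j], float(self.C[i, j]))

    def mean_r2_of(self, gene: str) -> float:
        return self.per_gene[gene].mean_r2


def candidate_features(gene: str, regulators: RegulatorSet) -> list[str]:
    """Regulators usable as predictors for ``gene``: Psi minus the gene
    itself, in the regulator set's deterministic order."""
    return [r for r in regulators.regulator_ids if r != gene]


def _derive_gene_seed(seed: int, gene: str) -> int:
    """Stable per-gene seed so parallel and serial execution agree."""
    return int(zlib.crc32(gene.encode(), seed & 0xFFFFFFFF)) % (2**31)


def _select(method: str, X: np.ndarray, y: np.ndarray, cfg, seed: int):
    if method == "omp":
        best_d0, fit = omp_select_d0(X, y, cfg, seed=seed)
        return fit
    if method == "en":
        _, _, fit = en_select(X, y, cfg, seed=seed)
        return fit
    raise ValueError(f"unknown method: {method}")


def _pooled_final_fit(method: str, X: np.ndarray, y: np.ndarray, cfg, outer_fits, seed: int):
    """Refit the final model on all rows at the hyperparameters maximizing
    the validation R^2 pooled across every outer split's inner CV.

    Each outer learning split already ran a full inner cross-validation;
    averaging their validation curves index-wise (repeated cross-validation)
    gives a lower-variance selection than any single split, and the final
    coefficients come from a refit on the complete dataset.
    """
    from .solvers import (
        en_alpha_grid,
        en_fit,
        omp_fit,
        standardize_columns,
        _unstandardize,
    )

    curves = [f.cv_mean_r2 for f in outer_fits if f.cv_mean_r2 is not None]
    Xs_all, mu_all, sd_all, keep_all = standardize_columns(X)
    y_mean = y.mean()
    p = X.shape[1]

    if method == "omp":
        if curves:
            m = min(c.shape[0] for c in curves)
            pooled = np.nanmean(np.vstack([c[:m] for c in curves]), axis=0)
            best_d0 = int(np.nanargmax(pooled)) if np.any(np.isfinite(pooled)) else 0
        else:
            best_d0 = 0
        fit_std = omp_fit(Xs_all[:, keep_all], y - y_mean, best_d0)
        hyper = {"d0": best_d0}
    else:
        y_sd = y.std()
        if y_sd > 0:
            basis = np.column_stack([Xs_all[:, keep_all], (y - y_mean) / y_sd])
        else:
            basis = Xs_all[:, keep_all]
        rho_grid = list(cfg.rho_grid)
        if curves:
            pooled = np.nanmean(np.stack(curves), axis=0)
            if np.any(np.isfinite(pooled)):
                best = np.nanmax(pooled)
                cands = [
                    (ri, ai)
                    for ri in range(pooled.shape[0])
                    for ai in range(pooled.shape[1])
                    if np.isfinite(pooled[ri, ai]) and pooled[ri, ai] == best
                ]
                best_ri, best_ai = max(cands, key=lambda t: (rho_grid[t[0]], -t[1]))
            else:
                best_ri, best_ai = len(rho_grid) - 1, 0
        else:
            best_ri, best_ai = len(rho_grid) - 1, 0
        best_rho = rho_grid[best_ri]
        grid = en_alpha_grid(basis, best_rho, cfg.K_alpha, cfg.epsilon)
        best_alpha = float(grid[best_ai])
        fit_std = en_fit(
            Xs_all[:, keep_all], y - y_mean, best_alpha, best_rho,
            seed=seed, max_iter=cfg.max_iter, tol=cfg.tol,
        )
        hyper = {"alpha": best_alpha, "rho": best_rho}

    coef_std = np.zeros(p)
    coef_std[keep_all] = fit_std.coefficients
    coef, intercept = _unstandardize(coef_std, y_mean, mu_all, sd_all, keep_all)
    from .solvers import FitResult

    return FitResult(coef, intercept, set(int(i) for i in np.flatnonzero(coef)), hyper)


def fit_gene(
    X: ExpressionMatrix,
    gene: str,
    regulators: RegulatorSet,
    method: str = "omp",
    cfg: OMPConfig | ENConfig | None = None,
    seed: int = 0,
    k_outer: int = 5,
) -> tuple[np.ndarray, GeneCVReport]:
    """Nested-CV fit for a single gene.

    The outer loop holds out each of ``k_outer`` condition folds in turn,
    runs the method's inner-CV selector on the learning split, and records
    the held-out validation R^2 and the wall-clock selection time.  The
    returned coefficient column (aligned to the regulator order) is the
    inner-CV-selected model refit on all conditions; ``mean_r2`` averages
    the outer validation scores.
    """
    if cfg is None:
        cfg = OMPConfig() if method == "omp" else ENConfig()
    features = candidate_features(gene, regulators)
    n_reg = len(regulators)
    flags: list[str] = []

    if not features:
        flags.append("no_candidates")
        report = GeneCVReport(gene, [], [], [], float("nan"), {}, 0.0, flags)
        return np.zeros(n_reg), report

    y = X.column(gene)
    if np.std(y) == 0.0:
        flags.append("constant_gene")
        report = GeneCVReport(gene, [], [], [], float("nan"), {}, 0.0, flags)
        return np.zeros(n_reg), report

    D = X.n_conditions
    if D < k_outer:
        raise ValueError(f"{D} conditions cannot be split into {k_outer} outer folds")

    Xf = X.columns(features)
    rng = np.random.default_rng(seed)
    folds = kfold_indices(D, k_outer, rng)

    outer_r2: list[float] = []
    outer_hp: list[dict] = []
    outer_rt: list[float] = []
    outer_fits = []
    for fi, val_idx in enumerate(folds):
        learn_idx = np.setdiff1d(np.arange(D), val_idx)
        t0 = time.perf_counter()
        fit = _select(method, Xf[learn_idx], y[learn_idx], cfg, seed=(seed * 31 + fi) % (2**31))
        outer_rt.append(time.perf_counter() - t0)
        pred = fit.predict(Xf[val_idx])
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            outer_r2.append(r2_score(y[val_idx], pred))
        outer_hp.append(dict(fit.selected_hyperparams))
        outer_fits.append(fit)

    t0 = time.perf_counter()
    final = _pooled_final_fit(
        method, Xf, y, cfg, outer_fits, seed=(seed * 31 + k_outer) % (2**31)
    )
    final_rt = time.perf_counter() - t0

    column = np.zeros(n_reg)
    reg_pos = {r: i for i, r in enumerate(regulators.regulator_ids)}
    for fj, feat in enumerate(features):
        column[reg_pos[feat]] = final.coefficients[fj]

    finite = [v for v in outer_r2 if np.isfinite(v)]
    mean_r2 = float(np.mean(finite)) if finite else float("nan")
    report = GeneCVReport(
        gene,
        outer_r2,
        outer_hp,
        outer_rt,
        mean_r2,
        dict(final.selected_hyperparams),
        final_rt,
        flags,
    )
    return column, report


def infer_gxn(
    X: ExpressionMatrix,
    regulators: RegulatorSet | None = None,
    method: str = "omp",
    cfg: OMPConfig | ENConfig | None = None,
    seed: int = 0,
    k_outer: int = 5,
) -> GXNModel:
    """Fit every gene's model and assemble the coefficient matrix.

    When no regulator list is given every gene is a potential regulator
    (Psi = Gamma).  Per-gene seeds are derived deterministically from the
    run seed and the gene identifier, so the result is independent of
    execution order and bit-identical across runs with the same seed.
    """
    if regulators is None:
        regulators = RegulatorSet(list(X.gene_ids))
    else:
        regulators = regulators.intersect(X)

    C = np.zeros((len(regulators), X.n_genes))
    per_gene: dict[str, GeneCVReport] = {}
    k_inner = (cfg.k_inner if cfg is not None else 5)
    for j, gene in enumerate(X.gene_ids):
        gene_seed = _derive_gene_seed(seed, gene)
        column, report = fit_gene(
            X, gene, regulators, method=method, cfg=cfg, seed=gene_seed, k_outer=k_outer
        )
        C[:, j] = column
        per_gene[gene] = report

    model = GXNModel(
        C=C,
        regulator_ids=list(regulators.regulator_ids),
        gene_ids=list(X.gene_ids),
        per_gene=per_gene,
        method_tag=method.upper(),
        k_inner=k_inner,
        k_outer=k_outer,
        seed=seed,
    )
    model.validate()
    return model


def filter_links_by_r2(
    model: GXNModel, threshold: float = 0.5
) -> list[tuple[str, str, float]]:
    """Keep edges whose target model generalizes: C[psi, g] != 0 and
    mean outer-validation R^2 strictly above ``threshold``.  Genes with an
    undefined R^2 contribute no edges."""
    kept = []
    for reg, gene, coef in model.edges():
        r2 = model.per_gene[gene].mean_r2
        if np.isfinite(r2) and r2 > threshold:
            kept.append((reg, gene, coef))
    return kept
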