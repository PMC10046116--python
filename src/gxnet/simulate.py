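"""Synthetic data with a planted, subspace-preserving regulatory model.

The generator emulates the union-of-subspaces structure the self-expressive
formalism assumes: genes fall into blocks, each block spanned by its own
regulators, and every target gene is an exact sparse linear combination of
regulators from its own block plus Gaussian noise.  Block regulators are
orthonormalized Gaussian latent profiles rescaled to unit variance, so the
block rank equals the number of regulators per block (which keeps the OMP
rank cap meaningful) and regulator columns are mutually uncorrelated in
expectation.  The planted coefficient matrix satisfies the same structural
constraints as an inferred model (zero diagonal, regulator rows only), so
fixtures and outputs are interchangeable in property tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .io import (
    AnnotationTable,
    ExpressionMatrix,
    GoldStandard,
    RegulatorSet,
    SampleClasses,
)


@dataclass
class PlantedScenario:
    """Ground-truth description of a synthetic dataset.

    Defaults give 3 expression blocks, 20 regulators total, 10 targets per
    block, 200 conditions, 3 true regulators per target and a noise
    standard deviation of 0.1 against unit-variance regulator profiles
    (signal-to-noise well above 10).
    """

    n_blocks: int = 3
    regulators_per_block: tuple[int, ...] = (7, 7, 6)
    targets_per_block: int = 10
    n_conditions: int = 200
    support_size: int = 3
    coef_range: tuple[float, float] = (0.5, 1.5)
    noise_sd: float = 0.1
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.regulators_per_block, int):
            self.regulators_per_block = (self.regulators_per_block,) * self.n_blocks
        if len(self.regulators_per_block) != self.n_blocks:
            raise ValueError("need one regulator count per block")
        if any(r < 2 for r in self.regulators_per_block):
            raise ValueError("each block needs at least 2 regulators")
        if any(self.support_size > r for r in self.regulators_per_block):
            raise ValueError("support size exceeds a block's regulator count")
        if self.n_conditions < 2 * self.support_size:
            raise ValueError("need at least 2 * support_size conditions")
        if self.coef_range[0] <= 0:
            raise ValueError("coefficients must be bounded away from zero")

    @property
    def n_regulators(self) -> int:
        return sum(self.regulators_per_block)

    @property
    def n_genes(self) -> int:
        return self.n_regulators + self.n_blocks * self.targets_per_block


def simulate_subspace_expression(
    scenario: PlantedScenario,
) -> tuple[ExpressionMatrix, RegulatorSet, GoldStandard, dict[str, int]]:
    """Draw a synthetic expression matrix with a planted sparse model.

    Returns the expression matrix (regulator columns first, then targets),
    the regulator set, a dense gold standard whose true links are exactly
    the planted support edges, and the gene -> block map.
    """
    rng = np.random.default_rng(scenario.seed)
    D = scenario.n_conditions
    reg_ids: list[str] = []
    tgt_ids: list[str] = []
    reg_cols: list[np.ndarray] = []
    tgt_cols: list[np.ndarray] = []
    block_map: dict[str, int] = {}
    true_links: set[tuple[str, str]] = set()
    planted_support: dict[str, list[str]] = {}

    block_regs: list[list[str]] = []
    for b, n_reg in enumerate(scenario.regulators_per_block):
        latent = rng.normal(size=(D, n_reg))
        q, _ = np.linalg.qr(latent)
        profiles = q[:, :n_reg] * np.sqrt(D)  # unit-variance orthogonal columns
        ids = [f"B{b}R{i}" for i in range(n_reg)]
        block_regs.append(ids)
        for i, rid in enumerate(ids):
            reg_ids.append(rid)
            reg_cols.append(profiles[:, i])
            block_map[rid] = b

    reg_col_of = dict(zip(reg_ids, reg_cols))
    lo, hi = scenario.coef_range
    for b in range(scenario.n_blocks):
        for t in range(scenario.targets_per_block):
            gid = f"B{b}T{t}"
            support = list(
                rng.choice(block_regs[b], size=scenario.support_size, replace=False)
            )
            coefs = rng.uniform(lo, hi, size=scenario.support_size)
            coefs *= rng.choice([-1.0, 1.0], size=scenario.support_size)
            col = sum(c * reg_col_of[r] for c, r in zip(coefs, support))
            if scenario.noise_sd > 0:
                col = col + rng.normal(scale=scenario.noise_sd, size=D)
            tgt_ids.append(gid)
            tgt_cols.append(np.asarray(col, dtype=float))
            block_map[gid] = b
            planted_support[gid] = support
            for r in support:
                true_links.add((r, gid))

    gene_ids = reg_ids + tgt_ids
    values = np.column_stack(reg_cols + tgt_cols)
    condition_ids = [f"C{i}" for i in range(D)]
    X = ExpressionMatrix(values, condition_ids, gene_ids)
    regulators = RegulatorSet(reg_ids)
    gold = GoldStandard(
        true_links=true_links,
        tested_tfs=set(reg_ids),
        tested_genes=set(gene_ids),
        dense=True,
    )
    return X, regulators, gold, block_map


def planted_coefficients(
    scenario: PlantedScenario,
) -> tuple[np.ndarray, list[str], list[str]]:
    """Re-derive the planted coefficient matrix C* (regulators x genes) by
    block-restricted least squares on a noise-free draw of the scenario."""
    X, regulators, gold, _ = simulate_subspace_expression(scenario)
    reg_ids = list(regulators.regulator_ids)
    gene_ids = list(X.gene_ids)
    C = np.zeros((len(reg_ids), len(gene_ids)))
    reg_pos = {r: i for i, r in enumerate(reg_ids)}
    for tf, tg in gold.true_links:
        support = [a for (a, b) in gold.true_links if b == tg]
        A = X.columns(sorted(support))
        coef, *_ = np.linalg.lstsq(A, X.column(tg), rcond=None)
        for r, c in zip(sorted(support), coef):
            C[reg_pos[r], gene_ids.index(tg)] = c
    return C, reg_ids, gene_ids


def simulate_two_class(
    X: ExpressionMatrix,
    effect: float,
    member_genes,
    seed: int = 0,
    labels: tuple[str, str] = ("class0", "class1"),
) -> tuple[ExpressionMatrix, SampleClasses]:
    """Split conditions 50/50 into two classes and add ``effect`` to the
    member genes in the second class's samples."""
    if X.n_conditions < 4:
        raise ValueError("need at least 4 conditions for a two-class split")
    member_genes = list(member_genes)
    unknown = set(member_genes) - set(X.gene_ids)
    if unknown:
        raise ValueError(f"member genes absent from the matrix: {sorted(unknown)[:5]}")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(X.n_conditions)
    half = X.n_conditions // 2
    class1_rows = set(perm[:half].tolist())
    mapping = {
        c: (labels[1] if i in class1_rows else labels[0])
        for i, c in enumerate(X.condition_ids)
    }
    values = X.values.copy()
    member_idx = [X.gene_ids.index(g) for g in member_genes]
    if effect != 0 and member_idx:
        rows = sorted(class1_rows)
        values[np.ix_(rows, member_idx)] += effect
    Xp = ExpressionMatrix(values, list(X.condition_ids), list(X.gene_ids))
    return Xp, SampleClasses(mapping)


def simulate_annotations(
    block_map: dict[str, int],
    n_noise_terms: int = 5,
    seed: int = 0,
    leakage: float = 0.1,
    root_term: str = "T_ROOT",
) -> AnnotationTable:
    """Build a two-level synthetic ontology over the planted blocks.

    Each block gets one true term annotating its genes (plus a ``leakage``
    fraction of random outside genes); ``n_noise_terms`` extra terms
    annotate random gene subsets.  All terms hang directly under a single
    synthetic root.
    """
    rng = np.random.default_rng(seed)
    genes = sorted(block_map)
    gene_to_terms: dict[str, set[str]] = {g: set() for g in genes}
    parents: dict[str, set[str]] = {}
    blocks: dict[int, list[str]] = {}
    for g, b in block_map.items():
        blocks.setdefault(b, []).append(g)
    for b, members in sorted(blocks.items()):
        term = f"T_BLOCK{b}"
        parents[term] = {root_term}
        for g in members:
            gene_to_terms[g].add(term)
        outside = [g for g in genes if block_map[g] != b]
        n_leak = int(round(leakage * len(members)))
        if n_leak and outside:
            for g in rng.choice(outside, size=min(n_leak, len(outside)), replace=False):
                gene_to_terms[str(g)].add(term)
    for t in range(n_noise_terms):
        term = f"T_NOISE{t}"
        parents[term] = {root_term}
        size = max(2, int(rng.integers(2, max(3, len(genes) // 3 + 1))))
        for g in rng.choice(genes, size=min(size, len(genes)), replace=False):
            gene_to_terms[str(g)].add(term)
    gene_to_terms = {g: ts for g, ts in gene_to_terms.items() if ts}
    return AnnotationTable(gene_to_terms, parents)
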