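"""Community-level enrichment statistics.

Two complementary analyses are provided for a partitioned network:

* a gene-set enrichment analysis (GSEA) asking whether a community's genes
  are collectively over- or under-expressed in a sample class, using the
  difference-of-classes gene ranking, the weighted Kolmogorov-Smirnov
  running-sum statistic (weight exponent 1) and a size-matched gene-set
  permutation null;
* a GO-style over-representation analysis (ORA) asking whether a
  community's genes are enriched for an ontology term, using the one-sided
  hypergeometric tail.

Both apply Benjamini-Hochberg FDR control and report only rows with raw p
and FDR below 0.05 (unless asked for the full table).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import hypergeom
from statsmodels.stats.multitest import multipletests

from .communities import CommunityPartition
from .io import AnnotationTable, ExpressionMatrix, SampleClasses


@dataclass
class GseaResult:
    community_id: int
    class_label: str
    es: float
    nes: float
    p: float
    fdr: float
    direction: str  # "over" | "under"
    n_genes: int


@dataclass
class OraResult:
    community_id: int
    term_id: str
    study_count: int
    study_size: int
    population_count: int
    population_size: int
    p: float
    fdr: float


# ---------------------------------------------------------------------------
# ranking and enrichment score
# ---------------------------------------------------------------------------


def rank_genes_diff_of_classes(
    X: ExpressionMatrix, classes: SampleClasses, target_class: str
) -> pd.Series:
    """Difference-of-classes gene scores, sorted descending.

    score(g) = mean expression of g in target-class samples minus the mean
    in all other samples.  Ties are ordered by gene id for determinism.
    """
    classes.validate_against(X)
    in_rows = [i for i, c in enumerate(X.condition_ids) if classes.mapping.get(c) == target_class]
    out_rows = [
        i
        for i, c in enumerate(X.condition_ids)
        if c in classes.mapping and classes.mapping[c] != target_class
    ]
    if len(in_rows) < 2 or len(out_rows) < 2:
        raise ValueError(
            f"class {target_class!r} and its complement each need >= 2 samples"
        )
    diff = X.values[in_rows].mean(axis=0) - X.values[out_rows].mean(axis=0)
    s = pd.Series(diff, index=X.gene_ids)
    order = sorted(range(len(s)), key=lambda i: (-s.iloc[i], s.index[i]))
    return s.iloc[order]


def _es_candidates(absw: np.ndarray, positions: np.ndarray, n: int) -> float:
    """Signed extremum of the running sum for hits at sorted ``positions``.

    ``absw`` holds |score| along the full ranking.  Hit increments are
    proportional to |score| (weight exponent 1, equal weights when all
    scores vanish); each miss decrements 1/(n - k).
    """
    k = positions.size
    if k == 0 or k >= n:
        raise ValueError("gene set must intersect the ranking strictly")
    hitw = absw[positions]
    nr = hitw.sum()
    if nr > 0:
        inc = hitw / nr
    else:
        inc = np.full(k, 1.0 / k)
    ch = np.cumsum(inc)
    j = np.arange(1, k + 1)
    miss = 1.0 / (n - k)
    after = ch - (positions + 1 - j) * miss
    before = (ch - inc) - (positions - (j - 1)) * miss
    cands = np.concatenate([after, before])
    ext = cands[np.argmax(np.abs(cands))]
    # deterministic sign on exact |max| = |min| ties: prefer the positive
    m = np.abs(cands).max()
    if ext < 0 and np.any(cands >= m):
        ext = m
    return float(ext)


def enrichment_score(ranked: pd.Series, gene_set) -> float:
    """Weighted Kolmogorov-Smirnov enrichment score in [-1, 1].

    ``ranked`` is a descending score series (as produced by
    :func:`rank_genes_diff_of_classes`); the score is the signed extremum
    of the running sum and is invariant under positive rescaling of the
    ranking scores.
    """
    genes = list(ranked.index)
    gene_set = set(gene_set)
    positions = np.array([i for i, g in enumerate(genes) if g in gene_set], dtype=int)
    n = len(genes)
    if positions.size == 0:
        raise ValueError("gene set does not intersect the ranking")
    if positions.size >= n:
        raise ValueError("gene set must be a strict subset of the ranking")
    absw = np.abs(ranked.to_numpy(dtype=float))
    return _es_candidates(absw, positions, n)


def _null_es(
    absw: np.ndarray, n: int, k: int, n_perm: int, rng: np.random.Generator
) -> np.ndarray:
    """Null ES for ``n_perm`` uniformly random size-k gene sets."""
    U = rng.random((n_perm, n))
    pos = np.sort(np.argpartition(U, k, axis=1)[:, :k], axis=1)
    out = np.empty(n_perm)
    for b in range(n_perm):
        out[b] = _es_candidates(absw, pos[b], n)
    return out


def gsea_community_test(
    X: ExpressionMatrix,
    classes: SampleClasses,
    partition: CommunityPartition,
    n_perm: int = 10_000,
    seed: int = 0,
    min_community_size: int = 3,
    significant_only: bool = True,
) -> list[GseaResult]:
    """One GSEA test per (community, class) pair.

    The null is the ES of size-matched gene sets drawn without replacement
    from the ranked universe (gene-set permutation).  p-values are
    two-tailed by sign: the observed |ES| is ranked among same-sign null ES
    with the (b+1)/(m+1) estimator, so p is never zero.  NES divides ES by
    the mean |null ES| of the same sign.  BH-FDR is applied across all
    (community, class) pairs; by default only rows with p < 0.05 and
    FDR < 0.05 are returned.
    """
    if n_perm < 100:
        raise ValueError("n_perm < 100 gives an unstable permutation null")
    comms = {
        cid: members
        for cid, members in partition.communities().items()
        if len(members) >= min_community_size
    }
    rows: list[GseaResult] = []
    raw_p: list[float] = []
    rng = np.random.default_rng(seed)
    for label in classes.labels():
        ranked = rank_genes_diff_of_classes(X, classes, label)
        genes = list(ranked.index)
        gene_pos = {g: i for i, g in enumerate(genes)}
        absw = np.abs(ranked.to_numpy(dtype=float))
        n = len(genes)
        null_cache: dict[int, np.ndarray] = {}
        for cid in sorted(comms):
            members = [g for g in comms[cid] if g in gene_pos]
            if not members:
                warnings.warn(f"community {cid} does not intersect the ranking; skipped")
                continue
            if len(members) >= n:
                continue
            positions = np.array(sorted(gene_pos[g] for g in members), dtype=int)
            es = _es_candidates(absw, positions, n)
            k = positions.size
            if k not in null_cache:
                null_cache[k] = _null_es(absw, n, k, n_perm, rng)
            null = null_cache[k]
            same_sign = null >= 0 if es >= 0 else null < 0
            m = int(same_sign.sum())
            b = int(np.sum(np.abs(null[same_sign]) >= abs(es)))
            p = (b + 1) / (m + 1)
            denom = float(np.mean(np.abs(null[same_sign]))) if m else np.nan
            nes = es / denom if denom and np.isfinite(denom) and denom > 0 else np.nan
            rows.append(
                GseaResult(
                    community_id=cid,
                    class_label=label,
                    es=es,
                    nes=nes,
                    p=p,
                    fdr=np.nan,
                    direction="over" if es >= 0 else "under",
                    n_genes=k,
                )
            )
            raw_p.append(p)
    if rows:
        fdr = multipletests([r.p for r in rows], method="fdr_bh")[1]
        for r, q in zip(rows, fdr):
            r.fdr = float(q)
    if significant_only:
        rows = [r for r in rows if r.p < 0.05 and r.fdr < 0.05]
    return rows


# ---------------------------------------------------------------------------
# GO over-representation
# ---------------------------------------------------------------------------


def go_overrepresentation(
    community_genes,
    population_genes,
    annotations: AnnotationTable,
    root_term: str,
    alpha: float = 0.05,
    significant_only: bool = True,
) -> list[OraResult]:
    """One-sided hypergeometric over-representation per ontology term.

    Tests every term annotating at least one population gene; BH-FDR runs
    across all tested terms, then reported rows are filtered to raw p and
    FDR below ``alpha`` and restricted to ``root_term`` and its descendants
    (transitive closure over the parent graph).
    """
    study = set(community_genes)
    population = set(population_genes)
    if not study <= population:
        raise ValueError("community genes must be a subset of the population")
    M = len(population)
    N = len(study)
    terms = sorted(annotations.terms())
    rows: list[OraResult] = []
    for term in terms:
        pop_hits = annotations.genes_for(term) & population
        K = len(pop_hits)
        if K == 0:
            continue
        k = len(pop_hits & study)
        p = float(hypergeom.sf(k - 1, M, K, N))
        rows.append(OraResult(-1, term, k, N, K, M, p, np.nan))
    if rows:
        fdr = multipletests([r.p for r in rows], method="fdr_bh")[1]
        for r, q in zip(rows, fdr):
            r.fdr = float(q)
    if significant_only:
        allowed = annotations.descendants(root_term)
        rows = [r for r in rows if r.p < alpha and r.fdr < alpha and r.term_id in allowed]
    return rows


def ora_by_community(
    partition: CommunityPartition,
    population_genes,
    annotations: AnnotationTable,
    root_term: str,
    alpha: float = 0.05,
    min_community_size: int = 3,
) -> list[OraResult]:
    """Run the over-representation test for every community."""
    out: list[OraResult] = []
    for cid, members in sorted(partition.communities().items()):
        if len(members) < min_community_size:
            continue
        study = [g for g in members if g in set(population_genes)]
        if not study:
            continue
        for r in go_overrepresentation(study, population_genes, annotations, root_term, alpha):
            r.community_id = cid
            out.append(r)
    return out
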