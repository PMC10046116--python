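# Methods

## Model

The package treats GRN inference as a constrained self-expression problem.
Genes are assumed to lie in a union of low-dimensional expression
subspaces; each gene's profile X_{*,g} ∈ R^D is regressed on the profiles
of the candidate regulators Ψ, excluding the gene itself, so that nonzero
coefficients connect genes sharing a subspace.  Two structural constraints
are enforced by construction, not by penalty: C_{g,g} = 0 (a regulator may
not explain itself — otherwise every regulator model degenerates to the
identity) and C_{j,g} = 0 for j ∉ Ψ (only regulators are predictive
features).  The assembled matrix C is read as a directed network with an
edge (ψ, g) wherever C_{ψ,g} ≠ 0.

Interpreting C as a GRN rests on the assumption that regulators lying in
the same expression subspace as a target participate in its control.  The
models are *predictive* (they forecast unseen conditions), which is a
stronger demand than the feature-importance scores of correlation- or
tree-based GRN tools, but linearity and the subspace assumption are still
approximations of real transcriptional logic.

## Solvers

**OMP.**  Greedy forward selection: at each step the candidate with the
largest |correlation with the current residual| joins the support, all
selected coefficients are refit by least squares and the residual is
recomputed.  The budget d0 is selected by inner CV over 0..d0max with
d0max = min(⌊δ·p⌋, rank(X)); δ defaults to 0.5, the densest setting of
the range explored when the method was characterized (0.01–0.5 — smaller
δ gives sparser, faster, slightly less accurate models).  d0 = 0 (the
empty model) is an admissible candidate, so pure-noise targets can select
no regulators at all.  Numerical rank uses the standard singular-value
cutoff max(n,p)·eps·σ_max.  The greedy solve itself is delegated to
scikit-learn's OrthogonalMatchingPursuit; the unit tests check it against
a naive re-solve-per-step oracle.

**ElasticNet.**  Coordinate descent on
‖y − Xc‖²/(2D) + αρ‖c‖₁ + α(1−ρ)‖c‖²/2 with a seeded random coordinate
update order (scikit-learn's `selection="random"`), deterministic given
the seed.  The mixing grid defaults to ρ ∈ {0.8, 0.9, 0.99, 1}: large ρ
is deliberate, since sparse (subspace-preserving) solutions are the goal
and small ρ behaves like ridge.  The α path is log-spaced from
α_max = max_{i≠j}|X_iᵀX_j|/(Dρ) down to ε·α_max with ε = 1/K_α
(default K_α = 10, i.e. ε = 0.1; deeper paths fit denser models).  The
pairwise α_max is computed over the standardized candidate columns
*augmented with the standardized target*, which guarantees
|X_jᵀy|/D ≤ ρ·α_max for every candidate j and hence an exactly null
coefficient vector at the top of the path — the property that anchors the
grid.  A per-target |Xᵀy|-based α_max is the more common convention; the
pairwise bound dominates it, so the null-vector anchor survives, at the
cost of a slightly conservative (larger) starting α.  A perfectly
orthogonal design makes the pairwise bound vanish; the grid constructor
then raises a dedicated error naming the |Xᵀy| fallback rather than
silently producing a degenerate path.

**Standardization.**  Features are z-scored and the target centered with
statistics from the training rows only; final coefficients are mapped
back to the original feature scale, with the intercept implied by
centering.  The α_max formula is only scale-meaningful on standardized
columns, which is why standardization is built into the selectors rather
than left to the caller.  Constant columns are excluded from the candidate
set.

## Nested cross-validation

Conditions are shuffled once per gene (seeded) and split into k_outer = 5
folds; each learning split runs an inner k_inner = 5-fold CV over the
hyperparameter grid, and the selected model's validation R² on the
held-out outer fold is recorded, along with the wall-clock selection time.
A gene's `mean_r2` is the mean of its five outer validation scores —
computed on conditions never touched by selection, so it is an honest
generalization estimate.

The final coefficient column refits on **all** conditions at the
hyperparameters maximizing the validation-R² curve pooled (index-wise
mean) across the five outer splits' inner CVs.  Pooling is a form of
repeated cross-validation: a single inner CV's argmax has enough variance
to overshoot the OMP budget on a sizeable minority of targets, inflating
false edges, while the pooled curve averages five independent inner CVs
and selects markedly more stably.  The outer R² monitor is unaffected by
this choice.  Selection ties break toward parsimony: smallest d0, largest
ρ then largest α.

Per-gene seeds are derived as crc32(gene_id, run_seed), so results are
independent of execution order and bit-identical across runs.

Degenerate targets never abort a run: constant genes and genes whose only
candidate is themselves yield a zero column, a flag, and an undefined R².
R² itself follows the standard determination-coefficient convention
(1 for perfect prediction, 0 for the fold-mean predictor, unbounded
below, undefined for a constant truth).

## Link filter and topology

Edges are retained only from target models with mean validation
R² strictly above 0.5 (genes with undefined R² contribute nothing).  The
filter is the generalization-awareness mechanism: with every gene column
independently permuted, effectively all genes fall below it.  Topology
metrics follow the benchmark conventions: the candidate universe
|Efull| = |Ψ|·(|Γ|−1) (ordered pairs, no self-loops, Ψ ⊆ Γ), sparsity
= 100·|Efull∖E|/|Efull|, and degrees are unweighted counts even though
edges carry signed coefficients.

## Gold-standard evaluation

Evaluation mirrors the DREAM5 protocol.  Predictions are restricted to
the experimentally tested TF×gene universe (dense by default: unlisted
pairs inside the universe are tested negatives; a sparse mode keeps only
listed 0-rows as negatives).  Tested pairs the method did not predict are
appended at score 0 so the curves reach their corner; ties average in
AUROC (Mann–Whitney) and AUPR uses the average-precision step
convention.  Edge scores are |coefficient| because the gold standard does
not distinguish activation from repression.

## Communities

The quality function is a generalized directed modularity
Q = (1/|E|) Σ_{ψ≠g} [w(ψ,g) − r·deg⁺(ψ)·deg⁻(g)/|E|]·ζ(ψ,g) with
w = |C| on edges and 0 elsewhere, unweighted degrees in the null term,
and ζ indicating co-membership.  Reading the sum literally, co-clustered
*non-edges* contribute their negative null term; self-pairs ψ = g are
excluded (consistent with the edge universe), which makes the
all-singleton partition score exactly 0.  Taking |C| as the weight is a
choice: modularity is undefined for negative weights and the coefficient
sign encodes regulation direction, not connection strength.

Partitions come from greedy agglomeration (Clauset–Newman–Moore style):
from singletons, repeatedly merge the pair of communities with the
largest ΔQ — ties resolved toward the lexicographically smallest pair of
community representatives — until one community remains, then return the
best partition on the path with its Q recomputed from scratch.  The
implementation is a dense O(n³) merge loop, adequate for the network
sizes the package targets (thousands of nodes); it is exact on the
fixtures where exhaustive enumeration is feasible.

The resolution r is chosen by scanning r ∈ {0.5, 0.6, …, 5}, computing
each partition's expression SSE (squared deviations from community mean
profiles), smoothing the SSE sequence with a centered moving average of
window 5 (edge-truncated), and taking the Kneedle elbow of the decreasing
convex curve (maximal vertical gap below the descending chord of the
normalized curve; ties toward the smallest r).  A knee-free (e.g.
linear) curve triggers a warned fallback to the point of maximal
finite-difference curvature.  Note that on data where community means
represent members poorly the SSE keeps falling as communities shrink and
the elbow can land at high r; the scan table is always emitted so the
choice can be audited.

## Enrichment

**GSEA.**  Genes are ranked by difference of class means (one-vs-rest per
class label; ties ordered by gene id).  The statistic is the classic
weighted Kolmogorov–Smirnov running sum with weight exponent 1 (hit
increments ∝ |score|, miss decrements 1/(n−k)); ES is its signed
extremum and lies in [−1, 1], invariant under positive rescaling of the
ranking.  Significance uses gene-set permutation: n_perm size-matched
random sets (default 10,000; fewer than 100 is refused as unstable),
with a two-tailed-by-sign p-value — the observed |ES| ranked among
same-sign null ES with the (b+1)/(m+1) estimator, so p > 0 always.  NES
divides ES by the mean |null ES| of the same sign.  BH FDR runs across
all (community, class) pairs and reported rows satisfy both p < 0.05 and
FDR < 0.05.  Communities need ≥ 3 genes to be tested.  This is a
simplification of the original GSEA's NES-based FDR; it keeps the
dual p/FDR filter exact and calibrates correctly under label shuffling.

**ORA.**  One-sided hypergeometric over-representation per annotation
term, BH FDR across tested terms, rows kept at p and FDR < 0.05 and
restricted to the requested root term plus its descendants (transitive
closure over a simple term→parent table; no OBO parsing, no annotation
up-propagation — annotations are used as given).

## Synthetic data

The generator plants exactly the structure the model assumes, which is
what makes it a sharp correctness probe and a weak realism probe.  Blocks
of regulators are built from orthonormalized Gaussian latent profiles
rescaled to unit variance, so each block has full rank (the OMP rank cap
stays meaningful) and regulator columns are mutually near-orthogonal —
consequently regulator self-models honestly fail the R² filter instead of
contaminating precision.  Each target is an exact sparse combination of
its own block's regulators (support size 3 by default, coefficients
±[0.5, 1.5], so bounded away from zero) plus N(0, 0.1²) noise — a
signal-to-noise ratio well above 10 at the default 200 conditions and
(7, 7, 6) regulators over 3 blocks with 10 targets each.  The gold
standard is the planted support, dense over the full gene set.  Two-class
fixtures add a constant effect to member genes in a random half of the
conditions; annotation fixtures give each block one true term (plus
optional leakage and noise terms) under a single synthetic root.

What passing on this generator does **not** show: robustness to
nonlinear regulation, correlated regulators within a block, measurement
batch effects, heavy-tailed count noise, or the much larger gene counts
of real compendia.  Real-data behavior is characterized by the benchmark
evaluation path, not by these fixtures.

## Numerical choices and defaults

| parameter | default | meaning |
|---|---|---|
| k_inner, k_outer | 5, 5 | CV folds (inner selects, outer monitors) |
| δ | 0.5 | OMP budget fraction of candidate count |
| ρ grid | {0.8, 0.9, 0.99, 1} | ElasticNet mixing values |
| K_α, ε | 10, 1/K_α | α-path length and depth |
| coordinate-descent tol / max_iter | 1e-6 / 10,000 | per-fit convergence |
| R² link filter | 0.5 (strict >) | generalization threshold |
| r grid | 0.5..5 step 0.1 | modularity resolution scan |
| SSE smoothing window | 5 (centered) | moving average before Kneedle |
| n_perm | 10,000 | GSEA gene-set permutations |
| significance | p < 0.05 and FDR < 0.05 | enrichment reporting filter |

The test suite and acceptance checks run the full pipeline at reduced
problem sizes chosen to exercise every code path while staying fast on a
single CPU: planted recovery uses 50 genes × 200 conditions over 10
seeds, and GSEA calibration uses 1,000 permutations over 50 communities ×
20 label shufflings.

## Known limitations

* Linear, static models: no time-course dynamics, no nonlinear effects.
* The greedy modularity maximizer is heuristic for large graphs; only on
  tiny fixtures is global optimality verified.
* The α_max pairwise bound can start the path conservatively high when the
  target is weakly correlated with all candidates.
* GSEA's FDR is BH over permutation p-values, not the original NES-based
  resampling FDR.
* Argmax hyperparameter selection (even pooled) retains a small
  overfitting probability under pure noise; the R² filter is the backstop.
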