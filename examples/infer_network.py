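"""Infer a gene self-expressive network on synthetic union-of-subspaces data.

Builds a small planted dataset (2 blocks of genes, each target an exact
sparse combination of its block's regulators plus noise), runs the OMP
variant with nested cross-validation, and reports how well the planted
regulatory edges are recovered after the generalization filter.
"""

import numpy as np

from gxnet import (
    OMPConfig,
    PlantedScenario,
    filter_links_by_r2,
    infer_gxn,
    network_from_model,
    simulate_subspace_expression,
    sparsity,
)

scenario = PlantedScenario(
    n_blocks=2,
    regulators_per_block=(5, 5),
    targets_per_block=8,
    n_conditions=120,
    support_size=3,
    noise_sd=0.1,
    seed=1,
)
X, regulators, gold, block_map = simulate_subspace_expression(scenario)
print(f"dataset: {X.n_conditions} conditions x {X.n_genes} genes, "
      f"{len(regulators)} regulators, {len(gold.true_links)} planted edges")

model = infer_gxn(X, regulators, method="omp", cfg=OMPConfig(delta=0.5), seed=0)
net = network_from_model(model)
kept = filter_links_by_r2(model, threshold=0.5)
tp = sum((a, b) in gold.true_links for a, b, _ in kept)

print(f"inferred edges (all nonzero coefficients): {net.n_edges}")
print(f"network sparsity: {sparsity(net):.2f}%")
print(f"edges surviving the R2>0.5 filter: {len(kept)}")
print(f"precision vs planted truth: {tp / len(kept):.3f}, "
      f"recall: {tp / len(gold.true_links):.3f}")
targets = [g for g in X.gene_ids if "T" in g]
mean_r2 = np.mean([model.per_gene[g].mean_r2 for g in targets])
print(f"mean outer-validation R2 over target genes: {mean_r2:.3f}")
# precision/recall near 1 show the sparse models picked exactly the planted
# regulators; the R2 is the honest out-of-sample variance explained.
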