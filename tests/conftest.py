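import numpy as np
import pytest

from gxnet import (
    ExpressionMatrix,
    PlantedScenario,
    simulate_subspace_expression,
)
from gxnet.topology import DirectedNetwork


@pytest.fixture(scope="session")
def small_scenario():
    return PlantedScenario(
        n_blocks=2,
        regulators_per_block=(4, 4),
        targets_per_block=4,
        n_conditions=80,
        support_size=2,
        noise_sd=0.05,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_dataset(small_scenario):
    return simulate_subspace_expression(small_scenario)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def random_network(rng, n_nodes=8, n_regs=5, p_edge=0.4):
    """A random directed regulator->gene network with positive weights."""
    nodes = [f"n{i}" for i in range(n_nodes)]
    regs = nodes[:n_regs]
    edges = []
    for r in regs:
        for g in nodes:
            if r != g and rng.random() < p_edge:
                edges.append((r, g, float(rng.uniform(0.2, 2.0)) * (1 if rng.random() < 0.5 else -1)))
    if not edges:
        edges.append((regs[0], nodes[-1], 1.0))
    return DirectedNetwork(nodes=nodes, regulators=regs, edges=edges)


@pytest.fixture
def two_cycle_network():
    """Two disjoint directed 3-cycles with unit weights; every node a regulator."""
    nodes = ["a", "b", "c", "x", "y", "z"]
    edges = [
        ("a", "b", 1.0), ("b", "c", 1.0), ("c", "a", 1.0),
        ("x", "y", 1.0), ("y", "z", 1.0), ("z", "x", 1.0),
    ]
    return DirectedNetwork(nodes=nodes, regulators=list(nodes), edges=edges)


def make_expression(rng, n_conditions=20, n_genes=10, prefix="g"):
    genes = [f"{prefix}{i}" for i in range(n_genes)]
    conds = [f"c{i}" for i in range(n_conditions)]
    return ExpressionMatrix(rng.normal(size=(n_conditions, n_genes)), conds, genes)
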