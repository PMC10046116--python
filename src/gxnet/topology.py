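"""Directed-network construction from the coefficient matrix and the
internal topology metrics: edge-universe size, sparsity, degree counts.

Degrees are unweighted counts even though edges carry coefficients: the
in-degree of a gene is the number of regulators in its regression model,
the out-degree of a regulator the number of target models that selected it.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import networkx as nx

from .engine import GXNModel, filter_links_by_r2


@dataclass
class DirectedNetwork:
    """A regulator -> gene network with nonzero edge weights, no self-loops."""

    nodes: list[str]
    regulators: list[str]
    edges: list[tuple[str, str, float]]

    def __post_init__(self) -> None:
        node_set = set(self.nodes)
        reg_set = set(self.regulators)
        if not reg_set <= node_set:
            raise ValueError("regulators must be a subset of the nodes")
        for src, dst, w in self.edges:
            if src == dst:
                raise ValueError(f"self-loop edge {src}->{dst}")
            if w == 0:
                raise ValueError(f"zero-weight edge {src}->{dst}")
            if src not in reg_set or dst not in node_set:
                raise ValueError(f"edge {src}->{dst} outside Psi x Gamma")

    @property
    def n_edges(self) -> int:
        return len(self.edges)


def network_from_model(
    model: GXNModel, r2_threshold: float | None = None
) -> DirectedNetwork:
    """Build the directed network encoded by C; with ``r2_threshold`` set,
    only links from generalizing target models are kept."""
    if r2_threshold is None:
        edges = list(model.edges())
    else:
        edges = filter_links_by_r2(model, r2_threshold)
    return DirectedNetwork(
        nodes=list(model.gene_ids),
        regulators=list(model.regulator_ids),
        edges=edges,
    )


def full_universe_size(n_genes: int, n_regulators: int) -> int:
    """|Efull| = |Psi| * (|Gamma| - 1): ordered regulator-gene pairs
    excluding self-loops, under the convention Psi is a subset of Gamma."""
    if n_regulators < 1 or n_genes < 1:
        raise ValueError("need at least one gene and one regulator")
    if n_regulators > n_genes:
        raise ValueError("more regulators than genes violates Psi subset of Gamma")
    return n_regulators * (n_genes - 1)


def sparsity(net: DirectedNetwork) -> float:
    """Percentage of the possible regulator-gene links absent from the
    network: 100 * |Efull \\ E| / |Efull|."""
    full = full_universe_size(len(net.nodes), len(net.regulators))
    if full == 0:
        raise ValueError("sparsity undefined for an empty edge universe")
    return 100.0 * (full - net.n_edges) / full


def degrees(net: DirectedNetwork) -> tuple[dict[str, int], dict[str, int]]:
    """(in_degree per gene, out_degree per regulator); both sums equal |E|."""
    in_deg = {g: 0 for g in net.nodes}
    out_deg = {r: 0 for r in net.regulators}
    for src, dst, _ in net.edges:
        out_deg[src] += 1
        in_deg[dst] += 1
    return in_deg, out_deg


def to_networkx(net: DirectedNetwork) -> nx.DiGraph:
    g = nx.DiGraph()
    g.add_nodes_from(net.nodes)
    for src, dst, w in net.edges:
        g.add_edge(src, dst, weight=abs(w), sign=1 if w > 0 else -1, coefficient=w)
    return g


def write_graphml(net: DirectedNetwork, path: str | Path) -> None:
    nx.write_graphml(to_networkx(net), str(path))
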