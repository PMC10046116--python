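import itertools
import warnings

import numpy as np
import pytest

from gxnet import (
    ExpressionMatrix,
    community_sse,
    generalized_modularity,
    greedy_partition,
    kneedle_elbow,
    moving_average,
    select_resolution,
)
from gxnet.communities import CommunityPartition
from gxnet.topology import DirectedNetwork, degrees

from conftest import random_network


def literal_modularity(net, membership, r):
    """Independent oracle: evaluate the quality function by its literal
    double sum over regulators and genes (self-pairs excluded)."""
    E = net.n_edges
    w = {}
    for a, b, c in net.edges:
        w[(a, b)] = w.get((a, b), 0.0) + abs(c)
    in_deg, out_deg = degrees(net)
    total = 0.0
    for g in net.nodes:
        for psi in net.regulators:
            if psi == g or membership[psi] != membership[g]:
                continue
            total += w.get((psi, g), 0.0) - r * out_deg[psi] * in_deg[g] / E
    return total / E


def set_partitions(items):
    """All set partitions (Bell-number enumeration)."""
    items = list(items)
    if not items:
        yield []
        return
    first, rest = items[0], items[1:]
    for part in set_partitions(rest):
        for i in range(len(part)):
            yield part[:i] + [[first] + part[i]] + part[i + 1 :]
        yield [[first]] + part


def planted_two_block_network(rng, block_size=3, intra_w=(0.8, 1.5), noise_edges=0):
    """Two dense blocks with random intra-block weights; every node is a
    regulator so directed cycles are possible."""
    nodes = [f"a{i}" for i in range(block_size)] + [f"b{i}" for i in range(block_size)]
    edges = []
    for prefix in ("a", "b"):
        members = [v for v in nodes if v.startswith(prefix)]
        for u, v in itertools.permutations(members, 2):
            edges.append((u, v, float(rng.uniform(*intra_w))))
    for _ in range(noise_edges):
        u, v = rng.choice(nodes, size=2, replace=False)
        edges = [e for e in edges if (e[0], e[1]) != (u, v)]
        edges.append((str(u), str(v), float(rng.uniform(0.05, 0.15))))
    return DirectedNetwork(nodes=nodes, regulators=list(nodes), edges=edges)


class TestGeneralizedModularity:
    def test_two_disjoint_cycles_exact_value(self, two_cycle_network):
        membership = {v: (0 if v in "abc" else 1) for v in two_cycle_network.nodes}
        # 6 intra edges of weight 1, all degrees 1: Q = (1/6) * sum over
        # intra pairs [w - r * 1 * 1 / 6]; intra pairs per community = 6
        # ordered non-self pairs, 3 of which are edges.
        q = generalized_modularity(two_cycle_network, membership, 1.0)
        expected = literal_modularity(two_cycle_network, membership, 1.0)
        assert q == pytest.approx(expected, abs=1e-12)
        # closed form: (6*1 - 1*(12)/6)/6  [12 ordered non-self intra pairs]
        assert q == pytest.approx((6 - 12 / 6) / 6, abs=1e-12)

    def test_single_community_closed_form(self, rng):
        net = random_network(rng)
        membership = {v: 0 for v in net.nodes}
        in_deg, out_deg = degrees(net)
        E = net.n_edges
        sum_w = sum(abs(w) for _, _, w in net.edges)
        null = sum(
            out_deg[p] * in_deg[g]
            for p in net.regulators
            for g in net.nodes
            if p != g
        )
        r = 0.7
        assert generalized_modularity(net, membership, r) == pytest.approx(
            (sum_w - r * null / E) / E, abs=1e-10
        )

    def test_singletons_score_zero(self, rng):
        net = random_network(rng)
        membership = {v: i for i, v in enumerate(net.nodes)}
        assert generalized_modularity(net, membership, 1.3) == 0.0

    def test_matches_literal_oracle_on_random_networks(self, rng):
        for _ in range(50):
            net = random_network(
                rng, n_nodes=int(rng.integers(4, 10)), n_regs=int(rng.integers(2, 5))
            )
            k = int(rng.integers(1, 4))
            membership = {v: int(rng.integers(0, k)) for v in net.nodes}
            r = float(rng.uniform(0.3, 3.0))
            assert generalized_modularity(net, membership, r) == pytest.approx(
                literal_modularity(net, membership, r), abs=1e-10
            )

    def test_empty_network_rejected(self):
        net = DirectedNetwork(nodes=["a", "b"], regulators=["a"], edges=[])
        with pytest.raises(ValueError):
            generalized_modularity(net, {"a": 0, "b": 0}, 1.0)


class TestGreedyPartition:
    def test_two_disconnected_blocks_recovered(self, rng):
        for r in (0.5, 1.0, 2.0):
            net = planted_two_block_network(rng)
            part = greedy_partition(net, r)
            groups = part.communities()
            assert part.n_communities == 2
            assert {frozenset(g) for g in groups.values()} == {
                frozenset({"a0", "a1", "a2"}),
                frozenset({"b0", "b1", "b2"}),
            }

    def test_beats_trivial_partitions(self, rng):
        for _ in range(10):
            net = random_network(rng, n_nodes=7, n_regs=4)
            part = greedy_partition(net, 1.0)
            q_single = generalized_modularity(net, {v: 0 for v in net.nodes}, 1.0)
            assert part.Q >= q_single - 1e-12
            assert part.Q >= 0.0 - 1e-12  # singletons score 0

    def test_attains_exhaustive_optimum_on_six_nodes(self, two_cycle_network, rng):
        nets = [two_cycle_network]
        for s in range(4):
            nets.append(planted_two_block_network(np.random.default_rng(s), noise_edges=2))
        for net in nets:
            assert len(net.nodes) == 6
            part = greedy_partition(net, 1.0)
            best = -np.inf
            count = 0
            for partition in set_partitions(net.nodes):
                count += 1
                membership = {v: i for i, block in enumerate(partition) for v in block}
                best = max(best, generalized_modularity(net, membership, 1.0))
            assert count == 203  # Bell(6)
            assert part.Q == pytest.approx(best, abs=1e-10)

    def test_stored_q_self_consistent(self, rng):
        for _ in range(5):
            net = random_network(rng, n_nodes=10, n_regs=6)
            part = greedy_partition(net, 1.4)
            assert part.Q == pytest.approx(
                generalized_modularity(net, part.membership, 1.4), abs=1e-12
            )

    def test_recovers_planted_blocks_with_ari(self, rng):
        from sklearn.metrics import adjusted_rand_score

        scores = []
        for s in range(10):
            lrng = np.random.default_rng(900 + s)
            net = planted_two_block_network(lrng, block_size=4, noise_edges=3)
            part = greedy_partition(net, 1.0)
            truth = [0 if v.startswith("a") else 1 for v in sorted(net.nodes)]
            got = [part.membership[v] for v in sorted(net.nodes)]
            scores.append(adjusted_rand_score(truth, got))
        assert np.mean(scores) >= 0.9


class TestCommunitySse:
    def test_all_singletons_zero(self, rng):
        X = ExpressionMatrix(rng.normal(size=(5, 4)), [f"c{i}" for i in range(5)], list("abcd"))
        part = CommunityPartition({g: i for i, g in enumerate("abcd")}, 1.0, 0.0)
        assert community_sse(X, part) == 0.0

    def test_identical_genes_zero(self):
        col = np.array([1.0, 2.0, 3.0])
        X = ExpressionMatrix(np.column_stack([col, col]), ["c1", "c2", "c3"], ["a", "b"])
        part = CommunityPartition({"a": 0, "b": 0}, 1.0, 0.0)
        assert community_sse(X, part) == 0.0

    def test_hand_arithmetic(self):
        X = ExpressionMatrix(np.array([[0.0, 2.0], [0.0, 2.0]]), ["c1", "c2"], ["a", "b"])
        part = CommunityPartition({"a": 0, "b": 0}, 1.0, 0.0)
        # mean profile (1,1); each gene deviates by 1 in both conditions
        assert community_sse(X, part) == pytest.approx(4.0)


def reference_kneedle(x, y):
    """Independent straight-line implementation: max distance below the
    descending chord of the normalized curve."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xn = (x - x.min()) / (x.max() - x.min())
    yn = (y - y.min()) / (y.max() - y.min())
    gap = (1 - xn) - yn
    return int(np.argmax(gap)) if gap.max() > 0 else None


class TestResolutionSelection:
    def test_kneedle_matches_reference_on_reciprocal_curve(self):
        r = np.arange(0.5, 5.01, 0.1)
        sse = 1.0 / r
        smoothed = moving_average(sse, 5)
        got = kneedle_elbow(r, smoothed)
        assert got == reference_kneedle(r, smoothed)
        assert r[got] < 2.0  # elbow sits in the lower third of the grid

    def test_linear_curve_has_no_knee(self):
        r = np.arange(0.5, 5.01, 0.1)
        assert kneedle_elbow(r, 10 - r) is None

    def test_moving_average_window_truncates_at_edges(self):
        v = np.array([1.0, 2.0, 3.0, 4.0, 5.0, 6.0])
        sm = moving_average(v, 5)
        assert sm[0] == pytest.approx(np.mean(v[:3]))
        assert sm[2] == pytest.approx(np.mean(v[:5]))
        assert sm[-1] == pytest.approx(np.mean(v[3:]))

    def test_scan_on_planted_blocks(self, rng, small_dataset):
        X, regs, gold, bm = small_dataset
        net = planted_two_block_network(rng, block_size=4)
        # expression for these nodes: two correlated blocks
        D = 30
        base_a = rng.normal(size=D)
        base_b = rng.normal(size=D)
        cols, names = [], []
        for v in sorted(net.nodes):
            base = base_a if v.startswith("a") else base_b
            cols.append(base + rng.normal(scale=0.3, size=D))
            names.append(v)
        Xe = ExpressionMatrix(np.column_stack(cols), [f"c{i}" for i in range(D)], names)
        scan = select_resolution(Xe, net, tuple(np.round(np.arange(0.5, 5.01, 0.1), 1)))
        assert len(scan.r_grid) == len(scan.sse) == len(scan.n_communities)
        assert scan.chosen_partition.n_communities >= 2
        assert min(scan.sse) <= scan.sse[scan.r_grid.index(scan.chosen_r)] <= max(scan.sse)

    def test_grid_too_short_rejected(self, rng):
        net = planted_two_block_network(rng)
        X = ExpressionMatrix(
            rng.normal(size=(10, 6)), [f"c{i}" for i in range(10)], sorted(net.nodes)
        )
        with pytest.raises(ValueError):
            select_resolution(X, net, (0.5, 1.0, 1.5))

    def test_constant_sse_triggers_fallback_warning(self, rng, monkeypatch):
        net = planted_two_block_network(rng)
        X = ExpressionMatrix(
            rng.normal(size=(10, 6)), [f"c{i}" for i in range(10)], sorted(net.nodes)
        )
        import gxnet.communities as comm

        monkeypatch.setattr(comm, "community_sse", lambda X, p: 1.0)
        with pytest.warns(UserWarning, match="no knee"):
            scan = select_resolution(X, net, tuple(np.round(np.arange(0.5, 1.3, 0.1), 1)))
        assert scan.fallback_used
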