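"""Community detection on the inferred network.

The quality function is a generalized directed modularity with a
resolution parameter r:

    Q = (1/|E|) * sum_{g in Gamma, psi in Psi, psi != g}
            [ w(psi, g) - r * deg+(psi) * deg-(g) / |E| ] * zeta(psi, g)

where w(psi, g) = |C[psi, g]| for present edges and 0 otherwise, degrees
are unweighted counts, and zeta is 1 iff psi and g share a community.  The
sum runs over ALL ordered regulator-gene pairs except self-pairs, so
co-clustered non-edges contribute their (negative) null term.  Q is 0 for
the all-singleton partition.

Partitions come from greedy agglomerative (Clauset-Newman-Moore style)
merging: starting from singletons, repeatedly join the pair of communities
with the largest modularity gain until one community remains, then return
the partition along the merge path with maximal Q.  The resolution is
chosen automatically by scanning a grid of r values, computing the
expression sum-of-squared-errors of each partition, smoothing with a
centered moving average (window 5) and locating the elbow with the Kneedle
criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io import ExpressionMatrix
from .topology import DirectedNetwork, degrees


DEFAULT_R_GRID = tuple(np.round(np.arange(0.5, 5.0 + 1e-9, 0.1), 10))


@dataclass
class CommunityPartition:
    """Gene -> community assignment at resolution r with its modularity Q."""

    membership: dict[str, int]
    resolution: float
    Q: float

    def communities(self) -> dict[int, list[str]]:
        out: dict[int, list[str]] = {}
        for node, cid in self.membership.items():
            out.setdefault(cid, []).append(node)
        for cid in out:
            out[cid].sort()
        return out

    @property
    def n_communities(self) -> int:
        return len(set(self.membership.values()))

    def sizes(self) -> dict[int, int]:
        return {cid: len(m) for cid, m in self.communities().items()}


@dataclass
class ResolutionScan:
    """SSE-vs-resolution scan with the automatically chosen elbow r*."""

    r_grid: list[float]
    sse: list[float]
    smoothed_sse: list[float]
    n_communities: list[int]
    chosen_r: float
    chosen_partition: CommunityPartition
    fallback_used: bool = False
    partitions: list[CommunityPartition] = field(default_factory=list, repr=False)


def generalized_modularity(
    net: DirectedNetwork, membership: dict[str, int], r: float
) -> float:
    """Evaluate the generalized directed modularity of a partition."""
    E = net.n_edges
    if E == 0:
        raise ValueError("modularity undefined for an empty edge set")
    in_deg, out_deg = degrees(net)
    intra_w = 0.0
    for src, dst, w in net.edges:
        if membership[src] == membership[dst]:
            intra_w += abs(w)
    # null term aggregated per community; self-pairs psi == g excluded
    comm_out: dict[int, float] = {}
    comm_in: dict[int, float] = {}
    self_term: dict[int, float] = {}
    for reg in net.regulators:
        cid = membership[reg]
        comm_out[cid] = comm_out.get(cid, 0.0) + out_deg[reg]
        self_term[cid] = self_term.get(cid, 0.0) + out_deg[reg] * in_deg[reg]
    for node in net.nodes:
        cid = membership[node]
        comm_in[cid] = comm_in.get(cid, 0.0) + in_deg[node]
    null = 0.0
    for cid in set(membership.values()):
        null += comm_out.get(cid, 0.0) * comm_in.get(cid, 0.0) - self_term.get(cid, 0.0)
    return (intra_w - r * null / E) / E


def greedy_partition(net: DirectedNetwork, r: float) -> CommunityPartition:
    """Agglomerative modularity maximization with deterministic tie-breaks.

    Ties in the merge gain are broken toward the lexicographically smallest
    pair of community representatives (each community is represented by its
    smallest node label).  The returned partition is the one with maximal Q
    along the merge path; its stored Q is recomputed from scratch.
    """
    E = net.n_edges
    if E == 0:
        raise ValueError("cannot partition a network with no edges")
    nodes = sorted(net.nodes)
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    in_deg_map, out_deg_map = degrees(net)

    W = np.zeros((n, n))
    for src, dst, w in net.edges:
        W[idx[src], idx[dst]] += abs(w)
    A = W + W.T  # symmetric between-community weight
    np.fill_diagonal(A, 0.0)
    dout = np.array([out_deg_map.get(v, 0) for v in nodes], dtype=float)
    din = np.array([in_deg_map.get(v, 0) for v in nodes], dtype=float)

    comm_of = np.arange(n)
    active = np.ones(n, dtype=bool)
    reps = list(nodes)  # representative label per community slot

    Q = 0.0  # all-singleton partition
    best_Q = 0.0
    best_membership = comm_of.copy()

    for _ in range(n - 1):
        act = np.flatnonzero(active)
        sub = (
            A[np.ix_(act, act)]
            - (r / E) * (np.outer(dout[act], din[act]) + np.outer(din[act], dout[act]))
        ) / E
        np.fill_diagonal(sub, -np.inf)
        gain = np.max(sub)
        cand = np.argwhere(np.isclose(sub, gain, rtol=0.0, atol=0.0) | (sub == gain))
        pairs = []
        for ci, cj in cand:
            if ci < cj:
                a, b = act[ci], act[cj]
                pairs.append(tuple(sorted((reps[a], reps[b]))) + (a, b))
        pairs.sort()
        _, _, a, b = pairs[0]
        if reps[b] < reps[a]:
            a, b = b, a
        # merge b into a
        A[a, :] += A[b, :]
        A[:, a] += A[:, b]
        A[a, a] = 0.0
        dout[a] += dout[b]
        din[a] += din[b]
        active[b] = False
        comm_of[comm_of == b] = a
        Q += gain
        if Q > best_Q + 1e-12:
            best_Q = Q
            best_membership = comm_of.copy()

    # relabel communities densely, ordered by smallest member
    groups: dict[int, list[str]] = {}
    for i, v in enumerate(nodes):
        groups.setdefault(int(best_membership[i]), []).append(v)
    ordered = sorted(groups.values(), key=lambda ms: min(ms))
    membership = {v: cid for cid, ms in enumerate(ordered) for v in ms}
    Q_exact = generalized_modularity(net, membership, r)
    return CommunityPartition(membership, float(r), Q_exact)


def community_sse(X: ExpressionMatrix, partition: CommunityPartition) -> float:
    """Sum over communities of squared deviations of each member gene's
    expression profile from the community mean profile."""
    total = 0.0
    for members in partition.communities().values():
        block = X.columns(members)
        mean = block.mean(axis=1, keepdims=True)
        total += float(np.sum((block - mean) ** 2))
    return total


def moving_average(values: np.ndarray, window: int = 5) -> np.ndarray:
    """Centered moving average, truncated at the edges."""
    values = np.asarray(values, dtype=float)
    half = window // 2
    out = np.empty_like(values)
    for i in range(values.size):
        lo = max(0, i - half)
        hi = min(values.size, i + half + 1)
        out[i] = values[lo:hi].mean()
    return out


def kneedle_elbow(x: np.ndarray, y: np.ndarray) -> int | None:
    """Kneedle knee index for a decreasing convex curve.

    Normalizes the curve into the unit square and returns the index of the
    maximal vertical gap below the descending diagonal; ``None`` when the
    curve never dips below the diagonal (no knee).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        return None
    xn = (x - x[0]) / (x[-1] - x[0])
    span = y.max() - y.min()
    if span == 0:
        return None
    yn = (y - y.min()) / span
    diff = (1.0 - xn) - yn
    best = int(np.argmax(diff))
    if diff[best] <= 1e-12:
        return None
    return best


def select_resolution(
    X: ExpressionMatrix,
    net: DirectedNetwork,
    r_grid: tuple[float, ...] = DEFAULT_R_GRID,
    smoothing_window: int = 5,
) -> ResolutionScan:
    """Scan resolutions, smooth the SSE curve and pick the elbow.

    For each r the greedy partition and its expression SSE are computed;
    the SSE sequence is smoothed by a centered moving average and the
    Kneedle elbow selected (ties toward the smallest r).  When no knee
    exists the r of maximal finite-difference curvature is used instead,
    with a warning.
    """
    r_grid = tuple(float(r) for r in r_grid)
    if len(r_grid) < 8:
        raise ValueError("resolution grid needs at least 8 points")
    if any(b <= a for a, b in zip(r_grid, r_grid[1:])):
        raise ValueError("resolution grid must be strictly increasing")

    partitions = [greedy_partition(net, r) for r in r_grid]
    sse = [community_sse(X, p) for p in partitions]
    smoothed = moving_average(np.array(sse), smoothing_window)

    knee = kneedle_elbow(np.array(r_grid), smoothed)
    fallback = False
    if knee is None:
        fallback = True
        warnings.warn(
            "Kneedle found no knee in the SSE curve; "
            "falling back to the point of maximal curvature"
        )
        if len(smoothed) >= 3:
            curv = np.abs(np.diff(smoothed, 2))
            knee = int(np.argmax(curv)) + 1
        else:
            knee = 0

    return ResolutionScan(
        r_grid=list(r_grid),
        sse=list(map(float, sse)),
        smoothed_sse=list(map(float, smoothed)),
        n_communities=[p.n_communities for p in partitions],
        chosen_r=float(r_grid[knee]),
        chosen_partition=partitions[knee],
        fallback_used=fallback,
        partitions=partitions,
    )
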