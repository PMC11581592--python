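"""Weighted modularity and Louvain community detection, from scratch.

Modularity of a partition :math:`\\{c_i\\}` of a weighted undirected graph:

.. math::

    Q = \\frac{1}{2m} \\sum_{ij} \\Big[ A_{ij} - \\frac{k_i k_j}{2m} \\Big]
        \\, \\sigma(c_i, c_j)

where :math:`A_{ij}` is the edge weight, :math:`k_i = \\sum_j A_{ij}` the
node strength, :math:`m` half the total weight, and :math:`\\sigma` is 1
when both nodes share a community.  Self-loop convention: a loop of stored
weight :math:`w` enters the diagonal of :math:`A` as :math:`2w` (so it
counts once per traversal direction), its node's strength gains
:math:`2w`, and ``m`` gains :math:`w`; this is the convention under which
collapsing a community into a single super-node with a self-loop leaves
:math:`Q` exactly unchanged, which the aggregation phase of Louvain relies
on.  Equivalently

.. math::

    Q = \\sum_c \\Big[ \\frac{W_c}{m} - \\Big(\\frac{K_c}{2m}\\Big)^2 \\Big]

with :math:`W_c` the intra-community weight (each edge once, loops once)
and :math:`K_c` the summed strength.

The Louvain procedure alternates a local-move phase (each node greedily
re-assigned to the neighbouring community with the largest positive
modularity gain, in a seeded random sweep order) with an aggregation
phase (communities collapsed to super-nodes, internal weight becoming a
self-loop), until a full cycle improves modularity by less than
``min_gain``.  The resolution parameter is fixed at 1.
"""

from __future__ import annotations

import math
from typing import Dict, Hashable, List, Mapping, Tuple

import numpy as np

from .graph import FlowGraph, EmptyGraphError

__all__ = [
    "Partition",
    "modularity",
    "louvain",
    "brute_force_best_partition",
    "adjusted_rand_index",
    "aggregate_graph",
    "move_gain",
]

#: default absolute modularity-gain threshold for convergence
DEFAULT_MIN_GAIN = 1e-10


class Partition:
    """Assignment of every graph node to exactly one community label.

    Labels are small integers.  :meth:`canonicalize` renumbers communities
    0..C-1 in order of each community's smallest member (by sorted node
    order), which makes partitions comparable across runs.
    """

    def __init__(self, labels: Mapping[Hashable, int]):
        self._labels: Dict[Hashable, int] = dict(labels)

    def __getitem__(self, node) -> int:
        return self._labels[node]

    def __contains__(self, node) -> bool:
        return node in self._labels

    def __len__(self) -> int:
        return len(self._labels)

    def __iter__(self):
        return iter(self._labels)

    def __eq__(self, other) -> bool:
        if not isinstance(other, Partition):
            return NotImplemented
        return self.canonicalize()._labels == other.canonicalize()._labels

    def __repr__(self) -> str:
        return f"Partition({self.n_communities} communities, {len(self)} nodes)"

    @property
    def labels(self) -> Dict[Hashable, int]:
        return dict(self._labels)

    @property
    def nodes(self) -> List[Hashable]:
        return list(self._labels)

    @property
    def n_communities(self) -> int:
        return len(set(self._labels.values()))

    def members(self) -> Dict[int, List[Hashable]]:
        out: Dict[int, List[Hashable]] = {}
        for n, c in self._labels.items():
            out.setdefault(c, []).append(n)
        return out

    def same_community(self, a, b) -> bool:
        """The indicator sigma(c_a, c_b)."""
        return self._labels[a] == self._labels[b]

    def canonicalize(self) -> "Partition":
        """Renumber communities by their smallest member node (sorted order)."""
        order: Dict[int, int] = {}
        for node in sorted(self._labels, key=str):
            c = self._labels[node]
            if c not in order:
                order[c] = len(order)
        return Partition({n: order[c] for n, c in self._labels.items()})

    def relabel(self, mapping: Mapping[int, int]) -> "Partition":
        return Partition({n: mapping[c] for n, c in self._labels.items()})

    # -- serialization -------------------------------------------------
    def to_frame(self):
        import pandas as pd

        return pd.DataFrame(
            sorted(((str(n), c) for n, c in self._labels.items())),
            columns=["node", "community"],
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "Partition":
        import pandas as pd

        df = pd.read_csv(path)
        return cls(dict(zip(df["node"], df["community"].astype(int))))


# ---------------------------------------------------------------------
# modularity
# ---------------------------------------------------------------------

def modularity(graph: FlowGraph, partition: Partition | Mapping[Hashable, int]) -> float:
    """Exact modularity Q of ``partition`` on ``graph``.

    Raises
    ------
    EmptyGraphError
        If the graph's total weight is zero (Q undefined).
    KeyError
        If the partition does not cover every node.
    """
    labels = partition.labels if isinstance(partition, Partition) else dict(partition)
    m = graph.require_weight()
    for n in graph.nodes:
        if n not in labels:
            raise KeyError(f"partition does not cover node {n!r}")
    intra: Dict[int, float] = {}
    strength: Dict[int, float] = {}
    for n in graph.nodes:
        c = labels[n]
        strength[c] = strength.get(c, 0.0) + graph.strength(n)
    for a, b, w in graph.edges():
        if labels[a] == labels[b]:
            c = labels[a]
            intra[c] = intra.get(c, 0.0) + w
    q = 0.0
    for c, k in strength.items():
        q += intra.get(c, 0.0) / m - (k / (2.0 * m)) ** 2
    return q


# ---------------------------------------------------------------------
# Louvain
# ---------------------------------------------------------------------

def _index_graph(graph: FlowGraph):
    """Integer-indexed adjacency (loops stored once), strengths, m."""
    nodes = graph.nodes
    index = {n: i for i, n in enumerate(nodes)}
    adj: List[Dict[int, float]] = [{} for _ in nodes]
    for a, b, w in graph.edges():
        ia, ib = index[a], index[b]
        adj[ia][ib] = adj[ia].get(ib, 0.0) + w
        if ia != ib:
            adj[ib][ia] = adj[ib].get(ia, 0.0) + w
    k = np.zeros(len(nodes))
    for i, nbrs in enumerate(adj):
        for j, w in nbrs.items():
            k[i] += 2.0 * w if j == i else w
    m = sum(w for i, nbrs in enumerate(adj) for j, w in nbrs.items() if j >= i)
    # the sum above double-handles nothing: each undirected pair stored on
    # both endpoints, kept once via j >= i; loops stored once on i == i
    return adj, k, m


def move_gain(
    k_node: float,
    m: float,
    sigma_tot_target: float,
    w_node_target: float,
) -> float:
    """Modularity gain of inserting an isolated node into a community.

    ``sigma_tot_target`` is the community's summed strength excluding the
    node itself, and ``w_node_target`` the weight between the node and
    community members (the node's self-loop excluded).  Equals
    ``modularity(after) - modularity(before)`` for the insertion,
    recomputed from scratch.
    """
    return w_node_target / m - k_node * sigma_tot_target / (2.0 * m * m)


def _local_moves(adj, k, m, labels: np.ndarray, rng: np.random.Generator) -> bool:
    """One or more greedy sweeps; returns True if any node moved."""
    n = len(adj)
    sigma_tot: Dict[int, float] = {}
    for i in range(n):
        sigma_tot[labels[i]] = sigma_tot.get(labels[i], 0.0) + k[i]
    moved_any = False
    improved = True
    while improved:
        improved = False
        order = rng.permutation(n)
        for node in order:
            current = int(labels[node])
            # weights from node to each neighbouring community (loops excluded)
            w_com: Dict[int, float] = {}
            for j, w in adj[node].items():
                if j != node:
                    w_com[int(labels[j])] = w_com.get(int(labels[j]), 0.0) + w
            sigma_tot[current] -= k[node]
            best_c = current
            best_gain = move_gain(k[node], m, sigma_tot.get(current, 0.0),
                                  w_com.get(current, 0.0))
            for c in sorted(w_com):
                if c == current:
                    continue
                g = move_gain(k[node], m, sigma_tot.get(c, 0.0), w_com[c])
                # strict improvement required; ties keep the current
                # community, otherwise the smallest label wins (sorted sweep)
                if g > best_gain + 1e-15:
                    best_gain, best_c = g, c
            labels[node] = best_c
            sigma_tot[best_c] = sigma_tot.get(best_c, 0.0) + k[node]
            if best_c != current:
                improved = True
                moved_any = True
    return moved_any


def aggregate_graph(graph: FlowGraph, partition: Partition) -> FlowGraph:
    """Collapse each community to a super-node.

    Inter-community weights are summed; intra-community weight (including
    existing loops) becomes the super-node's self-loop.  Modularity of any
    coarser partition is preserved exactly under this construction.
    """
    agg = FlowGraph()
    for c in set(partition.labels.values()):
        agg.add_node(c, kind="community")
    for a, b, w in graph.edges():
        agg.add_edge(partition[a], partition[b], w)
    return agg


def _louvain_once(graph: FlowGraph, seed: int, min_gain: float):
    adj, k, m = _index_graph(graph)
    if m <= 0:
        raise EmptyGraphError("Louvain requires a graph with positive total weight")
    nodes = graph.nodes
    rng = np.random.default_rng(seed)
    # mapping from original node index to current community label
    membership = np.arange(len(nodes))
    q_trace: List[float] = []
    current_labels = {n: int(membership[i]) for i, n in enumerate(nodes)}
    q_prev = modularity(graph, current_labels)
    while True:
        labels = np.arange(len(adj))
        _local_moves(adj, k, m, labels, rng)
        # compress labels of the working (possibly aggregated) graph
        uniq = {c: i for i, c in enumerate(sorted(set(int(x) for x in labels)))}
        labels = np.array([uniq[int(c)] for c in labels])
        membership = labels[membership]
        current_labels = {n: int(membership[i]) for i, n in enumerate(nodes)}
        q_now = modularity(graph, current_labels)
        q_trace.append(q_now)
        if q_now - q_prev <= min_gain or len(uniq) == len(adj):
            break
        q_prev = q_now
        # aggregation phase
        n_com = len(uniq)
        new_adj: List[Dict[int, float]] = [{} for _ in range(n_com)]
        for i, nbrs in enumerate(adj):
            ci = int(labels[i])
            for j, w in nbrs.items():
                if j < i:
                    continue
                cj = int(labels[j])
                if i == j:
                    new_adj[ci][ci] = new_adj[ci].get(ci, 0.0) + w
                elif ci == cj:
                    new_adj[ci][ci] = new_adj[ci].get(ci, 0.0) + w
                else:
                    new_adj[ci][cj] = new_adj[ci].get(cj, 0.0) + w
                    new_adj[cj][ci] = new_adj[cj].get(ci, 0.0) + w
        adj = new_adj
        k = np.zeros(n_com)
        for i, nbrs in enumerate(adj):
            for j, w in nbrs.items():
                k[i] += 2.0 * w if j == i else w
    part = Partition({n: int(membership[i]) for i, n in enumerate(nodes)}).canonicalize()
    return part, q_trace


def louvain(
    graph: FlowGraph,
    seed: int = 0,
    min_gain: float = DEFAULT_MIN_GAIN,
    restarts: int = 1,
) -> Tuple[Partition, float]:
    """Louvain community detection; returns ``(partition, Q)``.

    ``restarts`` independent runs (seeds ``seed, seed+1, ...``) are
    performed and the highest-modularity partition kept; the sweep order
    within a run is a seeded shuffle, so results are reproducible.
    Per-level modularity is non-decreasing by construction.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    best: Tuple[Partition, float] | None = None
    for r in range(restarts):
        part, trace = _louvain_once(graph, seed + r, min_gain)
        q = trace[-1]
        if best is None or q > best[1] + 1e-15:
            best = (part, q)
    assert best is not None
    return best


# ---------------------------------------------------------------------
# brute-force oracle
# ---------------------------------------------------------------------

MAX_BRUTE_FORCE_NODES = 10


def _set_partitions(n: int):
    """All restricted-growth label vectors for n items (Bell(n) of them)."""
    def rec(prefix: List[int], mx: int):
        if len(prefix) == n:
            yield list(prefix)
            return
        for c in range(mx + 2):
            prefix.append(c)
            yield from rec(prefix, max(mx, c))
            prefix.pop()

    yield from rec([], -1)


def brute_force_best_partition(graph: FlowGraph) -> Tuple[Partition, float]:
    """Global modularity maximizer by exhaustive set-partition enumeration.

    Guarded to graphs with at most :data:`MAX_BRUTE_FORCE_NODES` nodes
    (Bell-number growth).  Ties are broken toward the canonically
    lexicographically smallest label vector, which the enumeration order
    yields for free.
    """
    nodes = graph.nodes
    if len(nodes) > MAX_BRUTE_FORCE_NODES:
        raise ValueError(
            f"brute force limited to {MAX_BRUTE_FORCE_NODES} nodes, got {len(nodes)}"
        )
    graph.require_weight()
    best_labels: List[int] | None = None
    best_q = -math.inf
    for labels in _set_partitions(len(nodes)):
        q = modularity(graph, dict(zip(nodes, labels)))
        if q > best_q + 1e-15:
            best_q = q
            best_labels = labels
    assert best_labels is not None
    return Partition(dict(zip(nodes, best_labels))).canonicalize(), best_q


# ---------------------------------------------------------------------
# adjusted Rand index
# ---------------------------------------------------------------------

def adjusted_rand_index(p1: Partition, p2: Partition) -> float:
    """Permutation-adjusted Rand index between two partitions.

    Computed from the pair-count contingency table; 1.0 for identical
    partitions, ~0 for independent ones.  Both partitions must cover the
    same node set.
    """
    if set(p1.nodes) != set(p2.nodes):
        raise ValueError("partitions cover different node sets")
    nodes = p1.nodes
    table: Dict[Tuple[int, int], int] = {}
    a_sizes: Dict[int, int] = {}
    b_sizes: Dict[int, int] = {}
    for n in nodes:
        key = (p1[n], p2[n])
        table[key] = table.get(key, 0) + 1
        a_sizes[p1[n]] = a_sizes.get(p1[n], 0) + 1
        b_sizes[p2[n]] = b_sizes.get(p2[n], 0) + 1

    def comb2(x: int) -> float:
        return x * (x - 1) / 2.0

    sum_comb = sum(comb2(v) for v in table.values())
    sum_a = sum(comb2(v) for v in a_sizes.values())
    sum_b = sum(comb2(v) for v in b_sizes.values())
    total = comb2(len(nodes))
    expected = sum_a * sum_b / total if total else 0.0
    max_index = (sum_a + sum_b) / 2.0
    if max_index == expected:
        return 1.0
    return (sum_comb - expected) / (max_index - expected)
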