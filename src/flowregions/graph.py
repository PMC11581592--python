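"""Weighted undirected flow graphs.

The central container for both detection phases: a symmetric, weighted
graph whose edge weights are patient volumes.  Self-loops are permitted
(phase-2 within-community transfers) and follow the standard undirected
convention: a loop of weight ``w`` is stored once, contributes ``w`` to the
total weight ``m`` and ``2 w`` to the strength of its node, so that
``sum(strengths) == 2 m`` always holds.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Hashable, Iterator, Mapping, Tuple

import pandas as pd

NodeId = Hashable

__all__ = ["FlowGraph", "EmptyGraphError"]


class EmptyGraphError(ValueError):
    """Raised when an operation needs a graph with positive total weight."""


@dataclass
class FlowGraph:
    """Symmetric weighted graph with node kinds.

    Parameters
    ----------
    kinds
        Optional map node id -> kind label (``"zip"``, ``"hospital"``,
        ``"community"``).  Nodes added through :meth:`add_edge` default to
        kind ``None``.
    """

    kinds: Dict[NodeId, object] = field(default_factory=dict)
    _adj: Dict[NodeId, Dict[NodeId, float]] = field(default_factory=dict)

    # -- construction -------------------------------------------------
    def add_node(self, node: NodeId, kind: object = None) -> None:
        self._adj.setdefault(node, {})
        if kind is not None or node not in self.kinds:
            self.kinds[node] = kind

    def add_edge(self, a: NodeId, b: NodeId, weight: float) -> None:
        """Accumulate ``weight`` onto the (undirected) edge ``{a, b}``.

        Zero-weight increments are ignored; negative weights are invalid.
        """
        if weight < 0:
            raise ValueError(f"negative edge weight {weight!r} on ({a}, {b})")
        if weight == 0:
            self.add_node(a)
            self.add_node(b)
            return
        self.add_node(a)
        self.add_node(b)
        self._adj[a][b] = self._adj[a].get(b, 0.0) + weight
        if a != b:
            self._adj[b][a] = self._adj[b].get(a, 0.0) + weight

    # -- queries ------------------------------------------------------
    @property
    def nodes(self) -> list:
        return list(self._adj)

    @property
    def n_nodes(self) -> int:
        return len(self._adj)

    def neighbors(self, node: NodeId) -> Mapping[NodeId, float]:
        return self._adj[node]

    def weight(self, a: NodeId, b: NodeId) -> float:
        return self._adj.get(a, {}).get(b, 0.0)

    def edges(self) -> Iterator[Tuple[NodeId, NodeId, float]]:
        """Yield each undirected edge once (self-loops included once)."""
        seen = set()
        for a, nbrs in self._adj.items():
            for b, w in nbrs.items():
                key = frozenset((a, b)) if a != b else (a, a)
                if key in seen:
                    continue
                seen.add(key)
                yield a, b, w

    def strength(self, node: NodeId) -> float:
        """k_i: sum of incident weights, self-loops counted twice."""
        s = 0.0
        for b, w in self._adj[node].items():
            s += 2.0 * w if b == node else w
        return s

    def strengths(self) -> Dict[NodeId, float]:
        return {n: self.strength(n) for n in self._adj}

    @property
    def total_weight(self) -> float:
        """m: sum over undirected edges, each counted once (loops once)."""
        return sum(w for _, _, w in self.edges())

    def require_weight(self) -> float:
        m = self.total_weight
        if m <= 0:
            raise EmptyGraphError("graph has zero total weight (m = 0)")
        return m

    def degree(self, node: NodeId) -> int:
        return len(self._adj[node])

    def __contains__(self, node: NodeId) -> bool:
        return node in self._adj

    # -- serialization ------------------------------------------------
    def to_edgelist(self) -> pd.DataFrame:
        """Edge-list frame with columns node_a, node_b, weight."""
        rows = [(a, b, w) for a, b, w in self.edges()]
        df = pd.DataFrame(rows, columns=["node_a", "node_b", "weight"])
        return df.sort_values(["node_a", "node_b"], kind="mergesort").reset_index(drop=True)

    def to_csv(self, path) -> None:
        self.to_edgelist().to_csv(path, index=False)

    @classmethod
    def from_edgelist(cls, df: pd.DataFrame, kinds: Mapping[NodeId, object] | None = None) -> "FlowGraph":
        g = cls()
        for a, b, w in df[["node_a", "node_b", "weight"]].itertuples(index=False):
            g.add_edge(a, b, float(w))
        if kinds:
            for n, k in kinds.items():
                if n in g:
                    g.kinds[n] = k
        return g

    @classmethod
    def from_csv(cls, path) -> "FlowGraph":
        return cls.from_edgelist(pd.read_csv(path))
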