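"""Undirected simple network container with string node identifiers.

Protein identifiers are treated as opaque strings; no ID normalisation is
attempted.  The container enforces the invariants every downstream stage
relies on: no self-loops, no duplicate or reversed duplicate edges, and
every edge endpoint present in the node set.
"""

from __future__ import annotations

from functools import cached_property
from itertools import combinations
from typing import Iterable, Iterator

import networkx as nx

Edge = tuple[str, str]


def norm_edge(u: str, v: str) -> Edge:
    """Canonical unordered representation of an edge: sorted 2-tuple."""
    return (u, v) if u <= v else (v, u)


class Network:
    """An undirected simple graph over string node identifiers."""

    def __init__(self, nodes: Iterable[str] = (), edges: Iterable[Edge] = ()):
        node_set = {str(n) for n in nodes}
        edge_set = set()
        for u, v in edges:
            u, v = str(u), str(v)
            if u == v:
                continue
            edge_set.add(norm_edge(u, v))
            node_set.add(u)
            node_set.add(v)
        self.nodes: frozenset[str] = frozenset(node_set)
        self.edges: frozenset[Edge] = frozenset(edge_set)

    # -- derived accessors -------------------------------------------------
    @cached_property
    def _adj(self) -> dict[str, frozenset[str]]:
        adj: dict[str, set[str]] = {n: set() for n in self.nodes}
        for u, v in self.edges:
            adj[u].add(v)
            adj[v].add(u)
        return {n: frozenset(s) for n, s in adj.items()}

    def neighbors(self, v: str) -> frozenset[str]:
        return self._adj[v]

    def degree(self, v: str) -> int:
        return len(self._adj[v])

    def has_edge(self, u: str, v: str) -> bool:
        return norm_edge(u, v) in self.edges

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.edges)

    def sorted_nodes(self) -> list[str]:
        return sorted(self.nodes)

    def all_pairs(self) -> Iterator[Edge]:
        """All unordered node pairs in deterministic (lexicographic) order."""
        return combinations(self.sorted_nodes(), 2)

    def non_edges(self) -> Iterator[Edge]:
        return (p for p in self.all_pairs() if p not in self.edges)

    # -- conversions -------------------------------------------------------
    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges)
        return g

    @classmethod
    def from_networkx(cls, g: nx.Graph) -> "Network":
        return cls((str(n) for n in g.nodes), ((str(u), str(v)) for u, v in g.edges))

    # -- dunder ------------------------------------------------------------
    def __eq__(self, other) -> bool:
        return (
            isinstance(other, Network)
            and self.nodes == other.nodes
            and self.edges == other.edges
        )

    def __hash__(self) -> int:
        return hash((self.nodes, self.edges))

    def __repr__(self) -> str:
        return f"Network(n_nodes={self.n_nodes}, n_edges={self.n_edges})"
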