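"""Exhaustive graphlet-orbit counting by connected-subgraph enumeration.

Every connected induced subgraph on 2..max_nodes vertices is visited exactly
once (ESU-style recursive extension); each occurrence is classified by a
precomputed orbit lookup table, so the per-subgraph cost is a dictionary
lookup plus a handful of counter increments.  One pass yields, jointly:

* node-GDVs   -- per node, a 73-vector of node-orbit touch counts
  (element 0 is the node's degree);
* edge-GDVs   -- per edge, a 68-vector of edge-orbit touch counts;
* pair-GDVs   -- per unordered node pair, a 49-vector of node-pair-orbit
  touch counts, where the pair's own edge status is masked out: an
  occurrence counts only if the induced subgraph stays connected after
  removing the (u,v) edge, and it is classified by the non-edge orbit of
  (u,v) in that masked subgraph.

The masking makes pair-GDVs comparable between edges and non-edges, which
is what lets one link-prediction score rank both missing and spurious
interactions.
"""

from __future__ import annotations

from collections import Counter
from itertools import combinations
from typing import Iterator

import numpy as np

from .catalog import GraphletCatalog, _pair_bit
from .network import Network, norm_edge

NodeGDV = np.ndarray  # length n_node_orbits, non-negative ints
PairGDV = np.ndarray  # length n_pair_orbits (indexed pair_orbit - 1)


class _Indexed:
    """Integer-indexed adjacency view of a Network (sorted node order)."""

    def __init__(self, net: Network):
        self.names = net.sorted_nodes()
        self.index = {n: i for i, n in enumerate(self.names)}
        self.adj: list[set[int]] = [set() for _ in self.names]
        for u, v in net.edges:
            iu, iv = self.index[u], self.index[v]
            self.adj[iu].add(iv)
            self.adj[iv].add(iu)


def _connected_subsets(
    adj: list[set[int]], max_size: int, root: int | None = None
) -> Iterator[tuple[int, ...]]:
    """Yield each connected subset of 2..max_size vertices exactly once.

    With ``root`` given, only subsets containing ``root`` are produced (the
    anchor ordering treats the root as the minimum vertex).
    """
    n = len(adj)
    anchors = range(n) if root is None else (root,)
    for v in anchors:
        def allowed(u: int) -> bool:
            return u > v if root is None else u != root

        sub = [v]
        in_sub = {v}
        closed = {v} | adj[v]  # sub plus its neighborhood: extension exclusivity
        ext = [u for u in adj[v] if allowed(u)]
        stack = [(sub, in_sub, closed, ext)]
        while stack:
            sub, in_sub, closed, ext = stack.pop()
            ext = list(ext)
            while ext:
                w = ext.pop()
                new_sub = sub + [w]
                yield tuple(sorted(new_sub))
                if len(new_sub) < max_size:
                    new_ext = list(ext)
                    new_closed = closed | adj[w]
                    for u in adj[w]:
                        if allowed(u) and u not in closed:
                            new_ext.append(u)
                    stack.append((new_sub, in_sub | {w}, new_closed, new_ext))


def _subset_mask(subset: tuple[int, ...], adj: list[set[int]]) -> int:
    """Adjacency bitmask of the induced subgraph on a sorted vertex subset."""
    mask = 0
    b = 0
    k = len(subset)
    for i in range(k):
        ai = adj[subset[i]]
        for j in range(i + 1, k):
            if subset[j] in ai:
                mask |= 1 << b
            b += 1
    return mask


def count_all(net: Network, catalog: GraphletCatalog):
    """One enumeration pass computing node-, edge-, and pair-GDVs jointly.

    Returns ``(node_gdvs, edge_gdvs, pair_gdvs)``: node_gdvs maps every node
    to its vector; edge_gdvs and pair_gdvs are sparse (pairs never touching
    an orbit are absent and implicitly all-zero).
    """
    ix = _Indexed(net)
    n = len(ix.names)
    node_counts = np.zeros((n, catalog.n_node_orbits), dtype=np.int64)
    edge_counts: Counter = Counter()
    pair_counts: Counter = Counter()

    lookup = catalog.lookup
    for subset in _connected_subsets(ix.adj, catalog.max_nodes):
        k = len(subset)
        entry = lookup(k, _subset_mask(subset, ix.adj))
        for pos, node in enumerate(subset):
            node_counts[node, entry.node_orbits[pos]] += 1
        for (i, j), orb in entry.edge_orbits:
            edge_counts[(subset[i], subset[j], orb)] += 1
        for (i, j), orb in entry.pair_orbits:
            pair_counts[(subset[i], subset[j], orb)] += 1

    node_gdvs = {name: node_counts[i] for i, name in enumerate(ix.names)}

    edge_gdvs: dict[tuple[str, str], np.ndarray] = {}
    for (i, j, orb), c in edge_counts.items():
        key = norm_edge(ix.names[i], ix.names[j])
        vec = edge_gdvs.get(key)
        if vec is None:
            vec = edge_gdvs[key] = np.zeros(catalog.n_edge_orbits, dtype=np.int64)
        vec[orb - 1] += c

    pair_gdvs: dict[tuple[str, str], np.ndarray] = {}
    for (i, j, orb), c in pair_counts.items():
        key = norm_edge(ix.names[i], ix.names[j])
        vec = pair_gdvs.get(key)
        if vec is None:
            vec = pair_gdvs[key] = np.zeros(catalog.n_pair_orbits, dtype=np.int64)
        vec[orb - 1] += c
    return node_gdvs, edge_gdvs, pair_gdvs


def count_node_gdvs(net: Network, catalog: GraphletCatalog) -> dict[str, NodeGDV]:
    """Node-GDV of every node: how many graphlets it touches at each node orbit."""
    ix = _Indexed(net)
    n = len(ix.names)
    counts = np.zeros((n, catalog.n_node_orbits), dtype=np.int64)
    lookup = catalog.lookup
    for subset in _connected_subsets(ix.adj, catalog.max_nodes):
        entry = lookup(len(subset), _subset_mask(subset, ix.adj))
        for pos, node in enumerate(subset):
            counts[node, entry.node_orbits[pos]] += 1
    return {name: counts[i] for i, name in enumerate(ix.names)}


def count_edge_gdvs(net: Network, catalog: GraphletCatalog) -> dict[tuple[str, str], np.ndarray]:
    """Edge-GDV of every edge; edges touching no 3+-node graphlet map to zeros."""
    _, edge_gdvs, _ = count_all(net, catalog)
    for e in net.edges:
        edge_gdvs.setdefault(e, np.zeros(catalog.n_edge_orbits, dtype=np.int64))
    return edge_gdvs


def _pair_vector(net: Network, u: str, v: str, catalog: GraphletCatalog, masked: bool) -> np.ndarray:
    if u == v:
        raise ValueError("u and v must differ")
    if u not in net.nodes or v not in net.nodes:
        raise ValueError(f"node pair ({u!r}, {v!r}) not fully contained in the network")
    ix = _Indexed(net)
    iu, iv = ix.index[u], ix.index[v]
    adj = [set(s) for s in ix.adj]
    if masked:
        adj[iu].discard(iv)
        adj[iv].discard(iu)
    counts = np.zeros(catalog.n_pair_orbits, dtype=np.int64)
    lookup = catalog.lookup
    for subset in _connected_subsets(adj, catalog.max_nodes, root=iu):
        if iv not in subset:
            continue
        entry = lookup(len(subset), _subset_mask(subset, adj))
        i, j = sorted((subset.index(iu), subset.index(iv)))
        for (a, b), orb in entry.non_edge_orbits:
            if (a, b) == (i, j):
                counts[orb - 1] += 1
                break
    return counts


def count_pair_gdv(net: Network, u: str, v: str, catalog: GraphletCatalog) -> PairGDV:
    """Node-pair-GDV of (u, v), edge status masked out.

    The result is identical whether or not (u, v) is an edge, provided the
    surrounding structure is the same.
    """
    return _pair_vector(net, u, v, catalog, masked=True)


def count_non_edge_gdv(net: Network, u: str, v: str, catalog: GraphletCatalog) -> np.ndarray:
    """Non-edge-GDV of an absent edge (u, v); errors if (u, v) is an edge."""
    if net.has_edge(u, v):
        raise ValueError(f"({u!r}, {v!r}) is an edge; non-edge-GDV is undefined")
    return _pair_vector(net, u, v, catalog, masked=False)
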