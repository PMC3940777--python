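"""Naive subset-enumeration oracle for graphlet-orbit counting.

Independent of the package's counting path: subsets come from
itertools.combinations, connectivity and graph isomorphism from networkx
(VF2), and orbit labels from the catalog's canonical representatives via an
explicit isomorphism mapping.  Results are cached per labelled subgraph
shape so the oracle stays usable on a hundred small graphs.
"""

from itertools import combinations

import networkx as nx
import numpy as np

from orbitlp.network import Network, norm_edge


def _rep_graphs(catalog):
    reps = {}
    for g in catalog.graphlets:
        graph = nx.Graph()
        graph.add_nodes_from(range(g.node_count))
        graph.add_edges_from(g.edges)
        reps[g.id] = graph
    return reps


def _match(sub: nx.Graph, catalog, reps):
    """Isomorphism from ``sub`` onto its catalog representative, via VF2."""
    for g in catalog.graphlets:
        if g.node_count != sub.number_of_nodes() or g.edge_count != sub.number_of_edges():
            continue
        gm = nx.isomorphism.GraphMatcher(sub, reps[g.id])
        if gm.is_isomorphic():
            return g, gm.mapping
    raise AssertionError("induced connected subgraph missing from the catalog")


def _shape_key(subset, adj):
    return tuple(
        (i, j)
        for i, a in enumerate(subset)
        for j, b in enumerate(subset)
        if i < j and b in adj[a]
    )


def oracle_counts(net: Network, catalog):
    """Node-GDVs and pair-GDVs of every node/pair by exhaustive subset testing."""
    nodes = net.sorted_nodes()
    adj = {n: net.neighbors(n) for n in nodes}
    reps = _rep_graphs(catalog)
    node_cache: dict = {}
    pair_cache: dict = {}

    node_gdvs = {n: np.zeros(catalog.n_node_orbits, dtype=np.int64) for n in nodes}
    pair_gdvs = {
        p: np.zeros(catalog.n_pair_orbits, dtype=np.int64) for p in net.all_pairs()
    }
    for k in range(2, catalog.max_nodes + 1):
        for subset in combinations(nodes, k):
            shape = (k, _shape_key(subset, adj))
            if shape not in node_cache:
                sub = nx.Graph()
                sub.add_nodes_from(range(k))
                sub.add_edges_from(shape[1])
                if not nx.is_connected(sub):
                    node_cache[shape] = None
                else:
                    g, mapping = _match(sub, catalog, reps)
                    node_cache[shape] = tuple(g.node_orbit_of[mapping[i]] for i in range(k))
            orbits = node_cache[shape]
            if orbits is None:
                continue
            for pos, node in enumerate(subset):
                node_gdvs[node][orbits[pos]] += 1
            # pair-GDV: mask each in-subset pair's own edge, reclassify
            for i, j in combinations(range(k), 2):
                pkey = (shape, i, j)
                if pkey not in pair_cache:
                    masked = nx.Graph()
                    masked.add_nodes_from(range(k))
                    masked.add_edges_from(e for e in shape[1] if e != (i, j))
                    if not nx.is_connected(masked):
                        pair_cache[pkey] = None
                    else:
                        g, mapping = _match(masked, catalog, reps)
                        a, b = sorted((mapping[i], mapping[j]))
                        pair_cache[pkey] = g.non_edge_orbit_of[(a, b)]
                orbit = pair_cache[pkey]
                if orbit is not None:
                    pair_gdvs[norm_edge(subset[i], subset[j])][orbit - 1] += 1
    return node_gdvs, pair_gdvs
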