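"""GDV counting: frozen examples, invariants, and brute-force oracle agreement."""

from itertools import combinations

import networkx as nx
import numpy as np
import pytest

from orbitlp.counting import (
    _connected_subsets,
    count_all,
    count_edge_gdvs,
    count_node_gdvs,
    count_non_edge_gdv,
    count_pair_gdv,
)
from orbitlp.network import Network

from oracle import oracle_counts


def test_k2_node_gdv(cat5):
    net = Network(edges=[("a", "b")])
    gdvs = count_node_gdvs(net, cat5)
    for v in "ab":
        assert gdvs[v][0] == 1
        assert gdvs[v][1:].sum() == 0


def test_triangle_node_gdv(cat5, triangle):
    # frozen from brute-force enumeration: each node touches 2 edges and 1 triangle
    gdvs = count_node_gdvs(triangle, cat5)
    for v in "abc":
        expected = np.zeros(73, dtype=int)
        expected[0] = 2
        expected[3] = 1
        assert (gdvs[v] == expected).all()


def test_path4_end_node_gdv(cat5, path4):
    # frozen from brute-force enumeration: end node a touches one edge (orbit 0),
    # one 3-node-path end (orbit 1), one 4-node-path end (orbit 4)
    gdvs = count_node_gdvs(path4, cat5)
    a = gdvs["a"]
    assert a[0] == 1 and a[1] == 1 and a[4] == 1
    assert a.sum() == 3


def test_empty_network(cat5):
    assert count_node_gdvs(Network(), cat5) == {}


def test_triangle_pair_gdv_equals_open_path_pair_gdv(cat5, triangle):
    """Masking makes the triangle's (a,b) identical to the 3-path's open pair."""
    p3 = Network(edges=[("a", "b"), ("b", "c")])
    tri_pair = count_pair_gdv(triangle, "a", "b", cat5)
    p3_pair = count_pair_gdv(p3, "a", "c", cat5)
    assert tri_pair[0] == 1
    assert (tri_pair == p3_pair).all()


def test_pair_gdv_isolated_pair_is_zero(cat5):
    net = Network(nodes=["u", "v"])
    assert count_pair_gdv(net, "u", "v", cat5).sum() == 0


def test_pair_gdv_argument_errors(cat5, triangle):
    with pytest.raises(ValueError):
        count_pair_gdv(triangle, "a", "a", cat5)
    with pytest.raises(ValueError):
        count_pair_gdv(triangle, "a", "zzz", cat5)


def test_non_edge_gdv_rejects_edges(cat5, triangle):
    with pytest.raises(ValueError):
        count_non_edge_gdv(triangle, "a", "b", cat5)


def test_path4_edge_orbits(cat5, path4):
    """Outer edges touch edge orbit 3 once, the middle edge orbit 4 once."""
    egdvs = count_edge_gdvs(path4, cat5)
    assert egdvs[("a", "b")][3 - 1] >= 1
    assert egdvs[("b", "c")][4 - 1] >= 1


def test_k2_edge_gdv_is_zero(cat5):
    net = Network(edges=[("a", "b")])
    egdvs = count_edge_gdvs(net, cat5)
    assert egdvs[("a", "b")].sum() == 0


def test_subset_enumeration_matches_brute_force(small_er):
    g = small_er.to_networkx()
    names = small_er.sorted_nodes()
    adj = [
        {names.index(m) for m in small_er.neighbors(n)} for n in names
    ]
    got = list(_connected_subsets(adj, 5))
    assert len(got) == len(set(got))
    brute = {
        s
        for k in range(2, 6)
        for s in combinations(range(len(names)), k)
        if nx.is_connected(g.subgraph(names[i] for i in s))
    }
    assert set(got) == brute


def test_anchored_enumeration_contains_root(small_er):
    names = small_er.sorted_nodes()
    adj = [{names.index(m) for m in small_er.neighbors(n)} for n in names]
    got = list(_connected_subsets(adj, 4, root=3))
    assert got and all(3 in s for s in got)
    assert len(got) == len(set(got))
    full = [s for s in _connected_subsets(adj, 4) if 3 in s]
    assert set(got) == set(full)


@pytest.mark.parametrize("seed", range(6))
def test_oracle_agreement_random_graphs(cat5, seed):
    """ESU counting equals the naive subset-enumeration oracle exactly."""
    rng = np.random.default_rng(seed)
    n = int(rng.integers(6, 12))
    net = Network.from_networkx(nx.gnp_random_graph(n, float(rng.uniform(0.2, 0.5)), seed=seed))
    node_gdvs, _, pair_gdvs = count_all(net, cat5)
    o_nodes, o_pairs = oracle_counts(net, cat5)
    for v in net.nodes:
        assert (node_gdvs[v] == o_nodes[v]).all()
    zero = np.zeros(cat5.n_pair_orbits, dtype=int)
    for p in net.all_pairs():
        assert (pair_gdvs.get(p, zero) == o_pairs[p]).all()


def test_gdv0_is_degree(cat5, small_er):
    gdvs = count_node_gdvs(small_er, cat5)
    for v in small_er.nodes:
        assert gdvs[v][0] == small_er.degree(v)


def test_orbit_occupancy_conservation(cat4, small_er):
    """Summed node-orbit touches = sum over graphlet occurrences of their sizes.

    Each occurrence of a k-node graphlet contributes exactly k node-orbit
    increments, so total node counts must be divisible accordingly: checked
    via the identity sum_nodes sum_orbits gdv = sum_k k * (#k-subgraphs)."""
    from orbitlp.counting import _Indexed, _connected_subsets, _subset_mask

    gdvs = count_node_gdvs(small_er, cat4)
    total = sum(int(g.sum()) for g in gdvs.values())
    ix = _Indexed(small_er)
    occ = sum(len(s) for s in _connected_subsets(ix.adj, cat4.max_nodes))
    assert total == occ


def test_pair_gdv_symmetry_and_masking(cat4, small_er):
    """pair-GDV is symmetric and invariant to adding/removing the pair's own edge."""
    pairs = list(small_er.all_pairs())[:8]
    for u, v in pairs:
        a = count_pair_gdv(small_er, u, v, cat4)
        b = count_pair_gdv(small_er, v, u, cat4)
        assert (a == b).all()
        if small_er.has_edge(u, v):
            flipped = Network(small_er.nodes, set(small_er.edges) - {(u, v) if u <= v else (v, u)})
        else:
            flipped = Network(small_er.nodes, set(small_er.edges) | {(u, v) if u <= v else (v, u)})
        c = count_pair_gdv(flipped, u, v, cat4)
        assert (a == c).all()
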