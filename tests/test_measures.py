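"""Graphlet LP scores: similarity bounds, centrality monotonicity, alpha mixing."""

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from orbitlp.baselines import sn
from orbitlp.evaluation import rank_pairs
from orbitlp.measures import (
    CombinedScoreConfig,
    combined_score_table,
    compute_orbit_weights,
    graphlet_densities,
    node_gdv_similarity,
    pair_gdv_centrality,
)
from orbitlp.network import Network


@pytest.fixture(scope="session")
def w5(cat5):
    return compute_orbit_weights(cat5)


def test_weights_are_in_unit_interval(w5):
    for w, o in ((w5.node_w, w5.node_o), (w5.pair_w, w5.pair_o)):
        assert (o >= 1).all()
        assert (w > 0).all() and (w <= 1).all()
    assert w5.node_o[0] == 1 and w5.node_w[0] == 1.0  # degree orbit depends only on itself


def test_densities(cat5):
    d = graphlet_densities(cat5)
    assert d.shape == (49,)
    assert (d > 0).all() and (d <= 1).all()
    assert d[0] == 1.0  # pair orbit 1 completes to the triangle


gdv_vectors = st.lists(st.integers(min_value=0, max_value=10**6), min_size=73, max_size=73)


@settings(max_examples=50, deadline=None)
@given(u=gdv_vectors, v=gdv_vectors)
def test_similarity_symmetric_and_bounded(w5, u, v):
    w = w5
    u = np.array(u)
    v = np.array(v)
    s_uv = node_gdv_similarity(u, v, w)
    s_vu = node_gdv_similarity(v, u, w)
    assert s_uv == pytest.approx(s_vu)
    assert 0.0 <= s_uv <= 1.0
    assert node_gdv_similarity(u, u, w) == pytest.approx(1.0)


def test_similarity_identity_iff_equal(w5):
    u = np.zeros(73, dtype=int)
    prev = 1.0
    for entry in (1, 10, 1000, 10**6):
        v = np.zeros(73, dtype=int)
        v[7] = entry
        s = node_gdv_similarity(u, v, w5)
        assert s < prev  # strictly decreasing in the diverging entry
        prev = s
    assert prev < 1.0


def test_similarity_length_mismatch(w5):
    with pytest.raises(ValueError):
        node_gdv_similarity(np.zeros(10), np.zeros(10), w5)


def test_centrality_zero_and_monotone(w5, cat5):
    d = graphlet_densities(cat5)
    zero = np.zeros(49, dtype=int)
    assert pair_gdv_centrality(zero, w5) == 0.0
    base = pair_gdv_centrality(zero, w5, d)
    for i in range(49):
        bumped = zero.copy()
        bumped[i] = 1
        assert pair_gdv_centrality(bumped, w5, d) > base


def test_alpha_endpoints_change_ranking_basis(cat5, w5):
    net = Network.from_networkx(nx.gnp_random_graph(12, 0.35, seed=5))
    t0 = combined_score_table(net, CombinedScoreConfig(alpha=0.0), cat5, w5)
    t1 = combined_score_table(net, CombinedScoreConfig(alpha=1.0), cat5, w5)
    th = combined_score_table(net, CombinedScoreConfig(alpha=0.5), cat5, w5)
    # affine in alpha: score(0.5) = (score(0) + score(1)) / 2 pairwise
    for p in t0.scores:
        assert th.scores[p] == pytest.approx(0.5 * (t0.scores[p] + t1.scores[p]))


def test_alpha1_g3_ranks_like_shared_neighbours():
    """With only the 3-node graphlet, pure centrality is a monotone transform
    of the shared-neighbour count, so the two rankings coincide exactly."""
    from orbitlp.catalog import build_catalog

    cat3 = build_catalog(3)
    for seed in (0, 1, 2):
        net = Network.from_networkx(nx.gnp_random_graph(14, 0.3, seed=seed))
        t_gdv = combined_score_table(
            net, CombinedScoreConfig(alpha=1.0, max_graphlet_nodes=3), cat3
        )
        assert rank_pairs(t_gdv) == rank_pairs(sn(net))


def test_weighted_equals_unweighted_for_g3():
    """The only 3-node pair-orbit graphlet is the triangle (density 1), so
    density weighting is a no-op there."""
    from orbitlp.catalog import build_catalog

    cat3 = build_catalog(3)
    net = Network.from_networkx(nx.gnp_random_graph(13, 0.3, seed=9))
    a = combined_score_table(net, CombinedScoreConfig(alpha=0.7, max_graphlet_nodes=3, weighted=True), cat3)
    b = combined_score_table(net, CombinedScoreConfig(alpha=0.7, max_graphlet_nodes=3, weighted=False), cat3)
    for p in a.scores:
        assert a.scores[p] == pytest.approx(b.scores[p])


def test_config_validation():
    with pytest.raises(ValueError):
        CombinedScoreConfig(alpha=1.5)
    with pytest.raises(ValueError):
        CombinedScoreConfig(max_graphlet_nodes=6)


def test_catalog_config_mismatch(cat5):
    net = Network(edges=[("a", "b")])
    with pytest.raises(ValueError):
        combined_score_table(net, CombinedScoreConfig(max_graphlet_nodes=4), cat5)


def test_weight_overrides(w5):
    from orbitlp.measures import apply_weight_overrides

    over = apply_weight_overrides(w5, node={3: 0.25}, pair={1: 0.5})
    assert over.node_w[3] == 0.25 and over.pair_w[0] == 0.5
    assert over.node_w[0] == w5.node_w[0]  # untouched entries preserved
    assert w5.node_w[3] != 0.25  # original is not mutated
    with pytest.raises(ValueError):
        apply_weight_overrides(w5, node={0: 1.5})
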