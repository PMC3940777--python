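"""Graphlet-based link-prediction scores.

Three ingredients, combined into one score per unordered node pair:

* **node-GDV-similarity** ``S(u,v)`` compares the graphlet degree vectors of
  the two endpoints.  Per orbit *i*,

  ``D_i = w_i * |ln(u_i + 1) - ln(v_i + 1)| / ln(max(u_i, v_i) + 2)``,

  the total distance is ``D = sum_i D_i / sum_i w_i`` and ``S = 1 - D``.
  Logarithms keep orbits whose counts differ by orders of magnitude from
  dominating.  ``w_i = 1 - log(o_i)/log(#orbits)`` down-weights redundant
  orbits, where ``o_i`` is the number of orbits whose touching is implied by
  touching orbit *i* (computed here by induced-subgraph orbit containment).

* **node-pair-GDV-centrality** ``C(u,v) = sum_i w_i * ln(c_i + 1)`` over the
  node-pair-GDV counts ``c_i``; the more graphlets a pair participates in,
  the higher its centrality.  The *density-weighted* variant multiplies each
  term by the edge density of the orbit's edge-completed graphlet, favouring
  shared cliques over shared paths.

* the **combined score** ``alpha * C_hat + (1 - alpha) * S``, where
  ``C_hat`` is the centrality min-max normalised to [0, 1] over all scored
  pairs of the network, so that the mixing weight ``alpha`` is comparable
  across networks.  ``alpha = 0`` is pure similarity, ``alpha = 1`` pure
  centrality; restricted to 3-node graphlets, ``alpha = 1`` ranks pairs
  identically to the shared-neighbours baseline.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np

from .catalog import GraphletCatalog, build_catalog
from .counting import count_all
from .network import Network


@dataclass(frozen=True)
class OrbitWeights:
    """Per-orbit redundancy weights for node orbits and node-pair orbits.

    ``node_o[i]`` counts the node orbits whose touching is implied by
    touching node orbit ``i`` (itself included); ``node_w`` derives from it
    as ``1 - log(o_i)/log(#node orbits)``, and likewise for pair orbits.
    """

    node_o: np.ndarray
    node_w: np.ndarray
    pair_o: np.ndarray
    pair_w: np.ndarray


def _weights_from_counts(o: np.ndarray, n_orbits: int) -> np.ndarray:
    if n_orbits <= 1:
        return np.ones_like(o, dtype=float)
    return 1.0 - np.log(o.astype(float)) / math.log(n_orbits)


def _node_dependency_counts(catalog: GraphletCatalog) -> np.ndarray:
    """o_i for node orbits via induced-subgraph orbit containment.

    Touching orbit *i* of graphlet G at node x implies touching, for every
    connected induced subgraph of G that contains x, the orbit x occupies
    there; o_i is the number of distinct orbits so implied.
    """
    o = np.ones(catalog.n_node_orbits, dtype=np.int64)
    for g in catalog.graphlets:
        k = g.node_count
        reps: dict[int, int] = {}
        for x in range(k):
            reps.setdefault(g.node_orbit_of[x], x)
        for orbit, x in reps.items():
            implied = set()
            for size in range(2, k + 1):
                for subset in combinations(range(k), size):
                    if x not in subset:
                        continue
                    entry = catalog.lookup(size, _induced_mask(g, subset))
                    if entry is None:
                        continue
                    implied.add(entry.node_orbits[subset.index(x)])
            o[orbit] = len(implied)
    return o


def _pair_dependency_counts(catalog: GraphletCatalog) -> np.ndarray:
    """o_i for node-pair orbits, from each orbit's open (non-edge) representative."""
    o = np.ones(catalog.n_pair_orbits, dtype=np.int64)
    for g in catalog.graphlets:
        k = g.node_count
        reps: dict[int, tuple[int, int]] = {}
        for pair, orbit in g.non_edge_orbit_of.items():
            reps.setdefault(orbit, pair)
        for orbit, (x, y) in reps.items():
            implied = set()
            for size in range(2, k + 1):
                for subset in combinations(range(k), size):
                    if x not in subset or y not in subset:
                        continue
                    entry = catalog.lookup(size, _induced_mask(g, subset))
                    if entry is None:
                        continue
                    i, j = sorted((subset.index(x), subset.index(y)))
                    implied.add(dict(entry.non_edge_orbits)[(i, j)])
            o[orbit - 1] = len(implied)
    return o


def _induced_mask(g, subset: tuple[int, ...]) -> int:
    mask = 0
    b = 0
    edge_set = set(g.edges)
    k = len(subset)
    for i in range(k):
        for j in range(i + 1, k):
            a, c = subset[i], subset[j]
            if ((a, c) if a < c else (c, a)) in edge_set:
                mask |= 1 << b
            b += 1
    return mask


def compute_orbit_weights(catalog: GraphletCatalog) -> OrbitWeights:
    """Redundancy weights ``w_i = 1 - log(o_i)/log(#orbits)`` for both orbit kinds."""
    node_o = _node_dependency_counts(catalog)
    pair_o = _pair_dependency_counts(catalog)
    return OrbitWeights(
        node_o=node_o,
        node_w=_weights_from_counts(node_o, catalog.n_node_orbits),
        pair_o=pair_o,
        pair_w=_weights_from_counts(pair_o, catalog.n_pair_orbits),
    )


def apply_weight_overrides(
    weights: OrbitWeights,
    node: dict[int, float] | None = None,
    pair: dict[int, float] | None = None,
) -> OrbitWeights:
    """Replace selected orbit weights with user-supplied values in (0, 1].

    ``node`` maps node-orbit indices (0-based) and ``pair`` maps pair-orbit
    indices (1-based, as numbered in the catalog) to replacement weights.
    Lets users substitute an alternative dependency-weight convention
    without recomputing anything else.
    """
    node_w = weights.node_w.copy()
    pair_w = weights.pair_w.copy()
    for idx, w in (node or {}).items():
        if not 0.0 < w <= 1.0:
            raise ValueError(f"weight for node orbit {idx} must be in (0, 1], got {w}")
        node_w[idx] = w
    for idx, w in (pair or {}).items():
        if not 0.0 < w <= 1.0:
            raise ValueError(f"weight for pair orbit {idx} must be in (0, 1], got {w}")
        pair_w[idx - 1] = w
    return OrbitWeights(node_o=weights.node_o, node_w=node_w, pair_o=weights.pair_o, pair_w=pair_w)


def graphlet_densities(catalog: GraphletCatalog) -> np.ndarray:
    """Per-pair-orbit density of the edge-completed graphlet, in (0, 1]."""
    d = np.zeros(catalog.n_pair_orbits)
    for po, info in catalog.pair_orbit_info.items():
        d[po - 1] = info.density
    return d


def node_gdv_similarity(gdv_u: np.ndarray, gdv_v: np.ndarray, weights: OrbitWeights) -> float:
    """Topological similarity of two node-GDVs, in [0, 1]; 1 iff identical."""
    if gdv_u.shape != gdv_v.shape or gdv_u.shape != weights.node_w.shape:
        raise ValueError(
            "GDV/weight length mismatch: %s vs %s vs %s"
            % (gdv_u.shape, gdv_v.shape, weights.node_w.shape)
        )
    u = gdv_u.astype(float)
    v = gdv_v.astype(float)
    w = weights.node_w
    d = w * np.abs(np.log(u + 1.0) - np.log(v + 1.0)) / np.log(np.maximum(u, v) + 2.0)
    return float(1.0 - d.sum() / w.sum())


def pair_gdv_centrality(
    pair_gdv: np.ndarray, weights: OrbitWeights, density: np.ndarray | None = None
) -> float:
    """Centrality of a node pair: weighted log-count of shared graphlets."""
    if pair_gdv.shape != weights.pair_w.shape:
        raise ValueError(
            "pair-GDV/weight length mismatch: %s vs %s" % (pair_gdv.shape, weights.pair_w.shape)
        )
    terms = weights.pair_w * np.log(pair_gdv.astype(float) + 1.0)
    if density is not None:
        terms = density * terms
    return float(terms.sum())


@dataclass(frozen=True)
class CombinedScoreConfig:
    """Configuration of the combined graphlet LP score.

    alpha mixes centrality (alpha) against similarity (1 - alpha);
    max_graphlet_nodes selects the amount of topology used (3, 4, or 5,
    i.e. 3-node, 3-4-node, or 3-5-node graphlets); weighted selects
    density-weighted centrality.
    """

    alpha: float = 0.8
    max_graphlet_nodes: int = 5
    weighted: bool = True

    def __post_init__(self):
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {self.alpha}")
        if self.max_graphlet_nodes not in (3, 4, 5):
            raise ValueError("max_graphlet_nodes must be 3, 4, or 5")


def combined_score_table(
    net: Network,
    cfg: CombinedScoreConfig = CombinedScoreConfig(),
    catalog: GraphletCatalog | None = None,
    weights: OrbitWeights | None = None,
):
    """Score every unordered node pair with the combined graphlet measure.

    ``score = alpha * C_hat + (1 - alpha) * S`` with C_hat the min-max
    normalised (density-weighted) node-pair-GDV-centrality and S the
    node-GDV-similarity of the endpoints.
    """
    from .baselines import PairScoreTable

    if catalog is None:
        catalog = build_catalog(cfg.max_graphlet_nodes)
    elif catalog.max_nodes != cfg.max_graphlet_nodes:
        raise ValueError(
            "catalog built for max_nodes=%d but config requests %d"
            % (catalog.max_nodes, cfg.max_graphlet_nodes)
        )
    if weights is None:
        weights = compute_orbit_weights(catalog)
    density = graphlet_densities(catalog) if cfg.weighted else None

    node_gdvs, _, pair_gdvs = count_all(net, catalog)
    names = net.sorted_nodes()
    gdv_matrix = np.stack([node_gdvs[n] for n in names]).astype(float)
    log_gdv = np.log(gdv_matrix + 1.0)
    w = weights.node_w
    w_sum = w.sum()

    pairs = list(net.all_pairs())
    zero_pair = np.zeros(catalog.n_pair_orbits, dtype=np.int64)
    index = {n: i for i, n in enumerate(names)}

    centrality = np.empty(len(pairs))
    similarity = np.empty(len(pairs))
    for p, (u, v) in enumerate(pairs):
        centrality[p] = pair_gdv_centrality(pair_gdvs.get((u, v), zero_pair), weights, density)
        iu, iv = index[u], index[v]
        d = (
            w
            * np.abs(log_gdv[iu] - log_gdv[iv])
            / np.log(np.maximum(gdv_matrix[iu], gdv_matrix[iv]) + 2.0)
        )
        similarity[p] = 1.0 - d.sum() / w_sum

    span = centrality.max() - centrality.min() if len(pairs) else 0.0
    if span > 0:
        c_hat = (centrality - centrality.min()) / span
    else:
        c_hat = np.zeros_like(centrality)
    combined = cfg.alpha * c_hat + (1.0 - cfg.alpha) * similarity

    tag = "gdv(alpha=%g,g3-%d,%s)" % (
        cfg.alpha,
        cfg.max_graphlet_nodes,
        "weighted" if cfg.weighted else "unweighted",
    )
    return PairScoreTable(scores=dict(zip(pairs, combined.tolist())), tag=tag)
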