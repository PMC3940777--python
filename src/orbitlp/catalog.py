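"""Canonical catalog of 2-5-node graphlets and their automorphism orbits.

A *graphlet* is a small connected induced subgraph pattern.  Every
topologically distinct position inside a graphlet is an *orbit* of its
automorphism group; orbits are enumerated separately for nodes, edges,
non-edges, and (reconciled) node pairs:

* **node orbits** -- classes of nodes; 73 of them over 2-5-node graphlets,
  numbered from 0 (the end of the single 2-node graphlet, so that orbit-0
  counts equal node degree).
* **edge orbits** -- classes of edges over 3-5-node graphlets; 68 of them,
  numbered from 1 (the 3-node path's edge).
* **non-edge orbits** -- classes of non-adjacent node pairs over 3-5-node
  graphlets; 49 of them, numbered from 1 (the 3-node path's open pair).
* **node-pair orbits** -- each non-edge orbit is *reconciled* with the edge
  orbit obtained by adding the missing edge ("edge completion"), yielding a
  position class for a node pair that is agnostic of its own edge status.
  There are 49 of them, in bijection with the non-edge orbits.

The catalog also precomputes, for every labelled connected graph on up to
``max_nodes`` vertices, the orbit identity of each of its positions, so that
subgraph counting reduces to a table lookup.

Orbit numbering is deterministic: graphlets are sorted by (node count, edge
count, descending degree sequence, canonical adjacency encoding) and orbits
within a graphlet by the degree signature of their representatives.  This
reproduces the conventional anchors: the 4-node path's end nodes are node
orbit 4 and its middle nodes orbit 5; its outer edges are edge orbit 3 and
its middle edge orbit 4; the triangle's edges are edge orbit 2, reconciled
with the 3-node path's non-edge orbit 1 into node-pair orbit 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import combinations, permutations

def _pairs(k: int) -> list[tuple[int, int]]:
    return list(combinations(range(k), 2))


def _pair_bit(k: int) -> dict[tuple[int, int], int]:
    return {p: b for b, p in enumerate(_pairs(k))}


def _edges_of(mask: int, k: int) -> list[tuple[int, int]]:
    return [p for b, p in enumerate(_pairs(k)) if (mask >> b) & 1]


def _is_connected(mask: int, k: int) -> bool:
    if k == 1:
        return True
    adj = [0] * k
    for (i, j) in _edges_of(mask, k):
        adj[i] |= 1 << j
        adj[j] |= 1 << i
    seen = 1
    frontier = 1
    while frontier:
        nxt = 0
        for i in range(k):
            if (frontier >> i) & 1:
                nxt |= adj[i]
        frontier = nxt & ~seen
        seen |= nxt
    return seen == (1 << k) - 1


def _permute_mask(mask: int, k: int, perm: tuple[int, ...]) -> int:
    """Relabel: node i of the input becomes node perm[i] of the output."""
    bit = _pair_bit(k)
    out = 0
    for (i, j) in _edges_of(mask, k):
        a, b = perm[i], perm[j]
        out |= 1 << bit[(a, b) if a < b else (b, a)]
    return out


def _canonical_form(mask: int, k: int) -> tuple[int, tuple[int, ...]]:
    """Minimal adjacency encoding over all relabellings, with one witness."""
    best = None
    best_perm = None
    for perm in permutations(range(k)):
        m = _permute_mask(mask, k, perm)
        if best is None or m < best:
            best, best_perm = m, perm
    return best, best_perm


def _automorphisms(mask: int, k: int) -> list[tuple[int, ...]]:
    return [p for p in permutations(range(k)) if _permute_mask(mask, k, p) == mask]


def _orbits_of(items, action) -> list[frozenset]:
    """Partition ``items`` into classes closed under each mapping in ``action``."""
    remaining = set(items)
    out = []
    while remaining:
        seed = remaining.pop()
        orbit = {seed}
        frontier = [seed]
        while frontier:
            x = frontier.pop()
            for f in action:
                y = f(x)
                if y not in orbit:
                    orbit.add(y)
                    frontier.append(y)
        remaining -= orbit
        out.append(frozenset(orbit))
    return out


@dataclass(frozen=True)
class Graphlet:
    """One canonical graphlet with its orbit partitions.

    ``node_orbit_of[i]`` is the global node-orbit index of canonical node
    ``i``; ``edge_orbit_of``/``non_edge_orbit_of`` map canonical position
    pairs to global orbit indices (empty for the 2-node graphlet's edge,
    which carries no edge orbit).
    """

    id: int
    node_count: int
    mask: int
    edges: tuple[tuple[int, int], ...]
    node_orbit_of: tuple[int, ...]
    edge_orbit_of: dict[tuple[int, int], int]
    non_edge_orbit_of: dict[tuple[int, int], int]

    @property
    def edge_count(self) -> int:
        return len(self.edges)

    @property
    def density(self) -> float:
        n = self.node_count
        return 2.0 * self.edge_count / (n * (n - 1))

    def degree(self, i: int) -> int:
        return sum(1 for e in self.edges if i in e)


@dataclass(frozen=True)
class PairOrbitInfo:
    """Reconciliation record for one node-pair orbit.

    The non-edge orbit lives in ``open_graphlet``; adding the missing edge
    produces ``closed_graphlet``, where the added edge sits in
    ``edge_orbit``.  ``density`` is the edge density of the closed graphlet,
    used by density-weighted centrality.
    """

    pair_orbit: int
    non_edge_orbit: int
    edge_orbit: int
    open_graphlet: int
    closed_graphlet: int
    density: float


@dataclass(frozen=True)
class _LookupEntry:
    """Orbit identities for one labelled connected graph on k positions."""

    graphlet: int
    node_orbits: tuple[int, ...]
    edge_orbits: tuple[tuple[tuple[int, int], int], ...]
    non_edge_orbits: tuple[tuple[tuple[int, int], int], ...]
    # pair orbit (or None when masking disconnects) for every position pair
    pair_orbits: tuple[tuple[tuple[int, int], int], ...]


@dataclass
class GraphletCatalog:
    max_nodes: int
    graphlets: list[Graphlet]
    n_node_orbits: int
    n_edge_orbits: int
    n_non_edge_orbits: int
    n_pair_orbits: int
    pair_orbit_info: dict[int, PairOrbitInfo]
    _lookup: dict[tuple[int, int], _LookupEntry] = field(repr=False, default_factory=dict)

    def lookup(self, k: int, mask: int) -> _LookupEntry | None:
        """Orbit table for the labelled k-node graph ``mask`` (None if disconnected)."""
        return self._lookup.get((k, mask))

    def dump_table(self) -> str:
        """Tab-separated reference table of the canonical numbering."""
        lines = ["graphlet\tnodes\tedges\tnode_orbits\tedge_orbits\tnon_edge_orbits"]
        for g in self.graphlets:
            lines.append(
                "G%d\t%d\t%s\t%s\t%s\t%s"
                % (
                    g.id,
                    g.node_count,
                    ";".join("%d-%d" % e for e in g.edges),
                    ",".join(map(str, g.node_orbit_of)),
                    ",".join("%d-%d:%d" % (i, j, o) for (i, j), o in sorted(g.edge_orbit_of.items())),
                    ",".join("%d-%d:%d" % (i, j, o) for (i, j), o in sorted(g.non_edge_orbit_of.items())),
                )
            )
        return "\n".join(lines) + "\n"


def _enumerate_canonical(max_nodes: int) -> list[tuple[int, int]]:
    """All non-isomorphic connected graphs on 2..max_nodes nodes, sorted."""
    reps: list[tuple[int, int]] = []  # (k, canonical mask)
    for k in range(2, max_nodes + 1):
        seen = set()
        for mask in range(1 << len(_pairs(k))):
            if not _is_connected(mask, k):
                continue
            cmask, _ = _canonical_form(mask, k)
            seen.add(cmask)
        reps.extend((k, m) for m in seen)

    def key(item):
        k, mask = item
        degs = [0] * k
        for (i, j) in _edges_of(mask, k):
            degs[i] += 1
            degs[j] += 1
        return (k, len(_edges_of(mask, k)), tuple(sorted(degs, reverse=True)), mask)

    return sorted(reps, key=key)


def build_catalog(max_nodes: int = 5) -> GraphletCatalog:
    """Enumerate the graphlet catalog up to ``max_nodes`` (3, 4, or 5) nodes.

    Orbit partitions are computed from explicitly enumerated automorphisms;
    node-pair orbits are built by completing each non-edge orbit with its
    missing edge and locating that edge's orbit in the completed graphlet.
    """
    if max_nodes not in (3, 4, 5):
        raise ValueError("max_nodes must be 3, 4, or 5 (got %r)" % (max_nodes,))

    reps = _enumerate_canonical(max_nodes)
    graphlets: list[Graphlet] = []
    next_node_orbit = 0
    next_edge_orbit = 1
    next_non_edge_orbit = 1
    canon_index: dict[tuple[int, int], int] = {}

    for gid, (k, mask) in enumerate(reps):
        canon_index[(k, mask)] = gid
        edges = tuple(_edges_of(mask, k))
        autos = _automorphisms(mask, k)
        degs = [sum(1 for e in edges if i in e) for i in range(k)]

        node_actions = [lambda x, p=p: p[x] for p in autos]

        def pair_actions_for(p):
            def f(pair, p=p):
                a, b = p[pair[0]], p[pair[1]]
                return (a, b) if a < b else (b, a)

            return f

        pair_actions = [pair_actions_for(p) for p in autos]

        node_orbits = _orbits_of(range(k), node_actions)
        node_orbits.sort(key=lambda o: (degs[min(o, key=lambda x: degs[x])], min(o)))
        node_orbit_of = [0] * k
        for orb in node_orbits:
            for x in orb:
                node_orbit_of[x] = next_node_orbit
            next_node_orbit += 1

        edge_orbit_of: dict[tuple[int, int], int] = {}
        non_edge_orbit_of: dict[tuple[int, int], int] = {}
        if k >= 3:
            def pair_key(orb):
                rep = min(orb)
                return (tuple(sorted((degs[rep[0]], degs[rep[1]]))), rep)

            e_orbits = _orbits_of(edges, pair_actions)
            e_orbits.sort(key=pair_key)
            for orb in e_orbits:
                for e in orb:
                    edge_orbit_of[e] = next_edge_orbit
                next_edge_orbit += 1

            non_edges = [p for p in _pairs(k) if p not in set(edges)]
            ne_orbits = _orbits_of(non_edges, pair_actions)
            ne_orbits.sort(key=pair_key)
            for orb in ne_orbits:
                for e in orb:
                    non_edge_orbit_of[e] = next_non_edge_orbit
                next_non_edge_orbit += 1

        graphlets.append(
            Graphlet(
                id=gid,
                node_count=k,
                mask=mask,
                edges=edges,
                node_orbit_of=tuple(node_orbit_of),
                edge_orbit_of=edge_orbit_of,
                non_edge_orbit_of=non_edge_orbit_of,
            )
        )

    # --- reconcile non-edge orbits with edge-completed edge orbits ---
    pair_orbit_info: dict[int, PairOrbitInfo] = {}
    used_edge_orbits: set[int] = set()
    for g in graphlets:
        bit = _pair_bit(g.node_count)
        seen_orbits: set[int] = set()
        for (i, j), ne_orbit in g.non_edge_orbit_of.items():
            if ne_orbit in seen_orbits:
                continue
            seen_orbits.add(ne_orbit)
            closed_mask = g.mask | (1 << bit[(i, j)])
            cmask, perm = _canonical_form(closed_mask, g.node_count)
            closed = graphlets[canon_index[(g.node_count, cmask)]]
            a, b = perm[i], perm[j]
            e_orbit = closed.edge_orbit_of[(a, b) if a < b else (b, a)]
            if e_orbit in used_edge_orbits:  # pragma: no cover - structural guarantee
                raise AssertionError("edge completion is not injective")
            used_edge_orbits.add(e_orbit)
            pair_orbit_info[ne_orbit] = PairOrbitInfo(
                pair_orbit=ne_orbit,
                non_edge_orbit=ne_orbit,
                edge_orbit=e_orbit,
                open_graphlet=g.id,
                closed_graphlet=closed.id,
                density=closed.density,
            )

    cat = GraphletCatalog(
        max_nodes=max_nodes,
        graphlets=graphlets,
        n_node_orbits=next_node_orbit,
        n_edge_orbits=next_edge_orbit - 1,
        n_non_edge_orbits=next_non_edge_orbit - 1,
        n_pair_orbits=len(pair_orbit_info),
        pair_orbit_info=pair_orbit_info,
    )
    cat._lookup = _build_lookup(cat, canon_index)
    return cat


def _build_lookup(
    cat: GraphletCatalog, canon_index: dict[tuple[int, int], int]
) -> dict[tuple[int, int], _LookupEntry]:
    """Orbit tables for every labelled connected graph on 2..max_nodes nodes."""
    edge_to_pair = {info.edge_orbit: po for po, info in cat.pair_orbit_info.items()}
    partial: dict[tuple[int, int], dict] = {}
    for k in range(2, cat.max_nodes + 1):
        bit = _pair_bit(k)
        for mask in range(1, 1 << len(_pairs(k))):
            if not _is_connected(mask, k):
                continue
            cmask, perm = _canonical_form(mask, k)
            g = cat.graphlets[canon_index[(k, cmask)]]
            node_orbits = tuple(g.node_orbit_of[perm[i]] for i in range(k))
            edge_orbits = {}
            non_edge_orbits = {}
            for (i, j) in _pairs(k):
                a, b = perm[i], perm[j]
                key = (a, b) if a < b else (b, a)
                if (mask >> bit[(i, j)]) & 1:
                    if k >= 3:
                        edge_orbits[(i, j)] = g.edge_orbit_of[key]
                else:
                    non_edge_orbits[(i, j)] = g.non_edge_orbit_of[key]
            partial[(k, mask)] = {
                "graphlet": g.id,
                "node_orbits": node_orbits,
                "edge_orbits": edge_orbits,
                "non_edge_orbits": non_edge_orbits,
            }

    lookup: dict[tuple[int, int], _LookupEntry] = {}
    for (k, mask), d in partial.items():
        bit = _pair_bit(k)
        pair_orbits = {}
        for (i, j) in _pairs(k):
            b = bit[(i, j)]
            if (mask >> b) & 1:
                open_mask = mask & ~(1 << b)
                open_entry = partial.get((k, open_mask))
                if open_entry is None:
                    continue  # masking the edge disconnects the subgraph
                pair_orbits[(i, j)] = open_entry["non_edge_orbits"][(i, j)]
            else:
                pair_orbits[(i, j)] = d["non_edge_orbits"][(i, j)]
        # sanity: the edge-completion map must agree with direct masking
        for (i, j), eo in d["edge_orbits"].items():
            if (i, j) in pair_orbits and edge_to_pair.get(eo) != pair_orbits[(i, j)]:
                raise AssertionError("pair-orbit reconciliation mismatch")
        lookup[(k, mask)] = _LookupEntry(
            graphlet=d["graphlet"],
            node_orbits=d["node_orbits"],
            edge_orbits=tuple(sorted(d["edge_orbits"].items())),
            non_edge_orbits=tuple(sorted(d["non_edge_orbits"].items())),
            pair_orbits=tuple(sorted(pair_orbits.items())),
        )
    return lookup
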