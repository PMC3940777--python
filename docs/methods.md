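# Methods

## Graphlets, orbits, and the catalog

A graphlet is a connected induced subgraph pattern on 2–5 nodes; there are
30 of them. Positions inside a graphlet are equivalence classes under its
automorphism group ("orbits"), computed here by explicit enumeration of all
node permutations that preserve the adjacency relation (at most 5! = 120
per graphlet). Four taxonomies are maintained:

* **node orbits** (73 over 2–5-node graphlets, numbered from 0): classes of
  nodes. Orbit 0 is the end of the single 2-node graphlet, so orbit-0
  counts equal node degree.
* **edge orbits** (68 over 3–5-node graphlets, numbered from 1): classes of
  edges. The 2-node graphlet's edge carries no orbit — an edge's catalog
  describes its *surrounding* structure, and a bare edge has none.
* **non-edge orbits** (49 over 3–5-node graphlets, numbered from 1):
  classes of non-adjacent node pairs.
* **node-pair orbits** (49): each non-edge orbit is *reconciled* with the
  edge orbit produced by adding the missing edge ("edge completion"). The
  map non-edge-orbit → edge-orbit is injective (removing an edge of the
  completed orbit recovers the open graphlet up to isomorphism), so pair
  orbits are in bijection with non-edge orbits and we reuse their indices
  1–49. The 68 − 49 = 19 edge orbits without a pair-orbit partner are
  exactly those whose edge is a bridge: masking such an edge disconnects
  the graphlet, so no comparable non-edge position exists.

**Canonical numbering.** Graphlets are sorted by (node count, edge count,
descending degree sequence, minimal adjacency encoding over relabellings);
orbits within a graphlet are sorted by representative degree (for pairs,
the sorted endpoint-degree signature), ties broken by canonical node index.
This yields the conventional anchor assignments — 4-node path ends/middles
at node orbits 4/5, its outer/middle edges at edge orbits 3/4, its
non-edges at 2/3, the triangle's edges at edge orbit 2 reconciled with the
3-node path's open pair (non-edge orbit 1) into node-pair orbit 1 — and is
otherwise a deterministic convention. Any fixed numbering gives identical
scores and rankings, because every measure sums over orbits;
`GraphletCatalog.dump_table()` emits the full reference table.

## Counting

Connected induced subgraphs are enumerated once each by recursive extension
(ESU): an anchor node plus an extension frontier restricted to
higher-ranked nodes outside the current neighbourhood. Each visited subset
is classified by a precomputed lookup table keyed on (size, adjacency
bitmask) — built once per catalog from the canonical representatives — so
per-occurrence work is a dictionary access plus counter increments. One
pass accumulates node-, edge-, and pair-GDVs jointly. Exhaustive counting
is exponential in the worst case but fast on sparse biological networks;
the loop is embarrassingly parallel should that ever be needed.

Pair-GDVs mask the pair's own edge: an occurrence on a subset S counts only
if the induced subgraph minus the (u,v) edge stays connected, and it is
classified by the non-edge orbit of (u,v) in that masked subgraph. This
makes the vector identical for an edge and a non-edge with the same
surroundings — the property that lets one score rank both missing and
spurious interactions. A correctness oracle (naive subset enumeration +
VF2 isomorphism, `tests/oracle.py`) checks both counts exactly on 100
seeded random graphs.

## Orbit-dependency weights

The weights `w_i = 1 − log(o_i)/log(#orbits)` require per-orbit dependency
counts `o_i`. We derive them from first principles: touching orbit *j* of
graphlet G at position x implies, for every connected induced subgraph of G
containing x, touching the orbit x occupies there; `o_j` is the number of
distinct orbits so implied (including *j*). This gives `o_0 = 1` (degree
depends on nothing else, `w_0 = 1`) and e.g. `o = 2` for both 3-node-path
orbits. Pair-orbit dependencies are computed the same way from each
orbit's open representative. The historical weight table for node orbits
was hand-derived and is not printed anywhere we can consume; our
programmatic definition is reproducible and order-compatible for the small
orbits, and a user-supplied weight table can override it. When a
restricted catalog has a single pair orbit (3-node graphlets), the weight
is defined as 1.

## Score definitions and numerical choices

* Natural logarithm throughout. The base cancels in the similarity ratio
  and uniformly rescales centrality, leaving every ranking unchanged.
* Centrality functional form `Σ_i d_i·w_i·ln(c_i+1)`: the logarithm
  prevents a single huge orbit count from dominating, mirroring the
  similarity measure's rationale; it is strictly increasing in every
  count. Density weighting uses the edge density (2E/(n(n−1))) of each
  pair orbit's edge-completed graphlet, so 4-cliques weigh 1 and 4-paths
  0.5. With 3-node graphlets only there is a single pair orbit whose
  completed graphlet is the triangle (density 1), which is why weighted
  and unweighted centralities coincide there and why α = 1 reproduces the
  shared-neighbours ranking.
* Centrality is min–max normalised over all scored pairs before the
  α-mix, because similarity is bounded in [0,1] while centrality is not;
  without a common scale intermediate α values would be meaningless
  across networks. A degenerate network where all centralities are equal
  normalises to 0.
* Similarity of two all-zero GDVs is 1 (identical vectors), consistent
  with the formula's limit.

## Evaluation harness

Noise replicates remove `round(fraction·|E|)` edges uniformly without
replacement (seeded; replicate r uses master seed + r). Every unordered
node pair is scored — including present edges, which de-noising may drop.
Rankings are deterministic: descending score, ties broken lexicographically
by pair. The confusion table is reported on the k = 0…100% grid (top
`round(k%·#pairs)` pairs predicted as edges), with precision at k = 0
defined as 1 and F = 0 when P + R = 0. AUROC and AUPR are integrated by
trapezoid over the *full ranking resolution* (one threshold per rank)
rather than the 1% grid: the areas are then exact — a perfect ranking
scores 1.0, a fully inverted one 0.0 — while the printed table keeps the
coarser grid for readability. Replicate summaries average per-replicate
areas (used by the paired t-test) and also pointwise-average the tables
for plotting. The paired t-test on per-replicate AUROCs returns p = 1 for
identical vectors and p = 0 for a constant non-zero offset (zero variance
of differences), flagging the degenerate case rather than erroring.

De-noising keeps the top-|E| ranked pairs as the new edge set over the
unchanged node set; de-noised networks are compared by shared-edge count
and edge-set Jaccard.

## Enrichment statistics

GO-sharing enrichment: eligible edges have both endpoints annotated; a hit
shares ≥ 1 term (direct set intersection, no ontology propagation). The
hypergeometric population is all annotated node pairs of the universe
network, successes are the sharing pairs, draws the eligible edges, and
the p-value is the upper tail P[X ≥ hits]. External validation draws from
the original network's non-edges over nodes shared with the reference,
with successes the reference's edges among them; predictions already
present in the original network are filtered out first. Both populations
are the only margins under which "edges drawn at random" is the exact
null; the test-suite calibration check confirms the resulting p-values
are stochastically ≥ uniform under simulated uniform draws.

## Synthetic fixtures

Generators cover Erdős–Rényi, Barabási–Albert, random geometric, and
ring-plus-chords models, with string node labels and full seed
determinism. Geometric graphs are the default PPI stand-in because their
clustering resembles physical interaction maps; none of the models
reproduces PPI degree-mixing, hub biology, or experimental ascertainment
bias, so passing tests demonstrate algorithmic correctness and calibration,
not biological performance on real interactomes. Annotation tables draw
1 + Poisson(λ−1) terms per gene; an assortativity knob in [0,1] propagates
a term across each edge with that probability, giving enrichment tests a
controllable signal (0 = no signal, 1 = every edge shares a term).

Routine tests use networks of ≤ 60 nodes, where 3–5-node counting takes a
few seconds; `fixtures.paper_scale_spec()` provides a ~1,000-node,
~8,000-edge profile (the size class of an AP/MS yeast interactome) for
benchmarking outside the test suite.

## Known limitations

* Exhaustive counting only; no sampling estimators, no graphlets beyond 5
  nodes, no directed graphlets.
* The random-walk-with-resistance baseline is not included (no
  self-contained published formula to implement against); externally
  computed scores can be imported via `orbitlp.io.read_scores` and ranked
  with the same harness.
* Edge-GDVs are counted and exposed, but no edge-GDV-similarity measure is
  built on them (it is not an LP measure).
* The orbit-dependency table and the density-weighting scheme are this
  package's own documented reconstructions; alternative weight tables can
  be supplied where other conventions are preferred.
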