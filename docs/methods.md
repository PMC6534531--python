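# Methods

## The model

A gene family is a rooted phylogenetic tree `(T, σ)`: leaves `L` are genes,
`σ : L → S` maps each gene to the species it resides in, and every inner
vertex other than (possibly) the root has at least two children.  Gene `y`
is a **best match** of gene `x` when `σ(y) ≠ σ(x)` and
`lca(x, y) ⪯ lca(x, y′)` for every gene `y′` of species `σ(y)` — no gene of
that species diverged from `x` more recently.  The **colored best match
graph** (cBMG) `G(T, σ)` records all best-match arcs, with vertices colored
by species.  This is the idealized object that reciprocal-best-hit
orthology pipelines approximate from sequence similarity; the package
deals with the combinatorial question of which colored digraphs can arise
this way at all, and how to reconstruct the least resolved tree (LRT) that
explains one.

Assumptions inherited from the model: the coloring is surjective, arcs
only join distinct colors, the graph is loop-free, and "connected" always
means weakly connected (cBMGs need not be strongly connected).  Branch
lengths, duplication/loss event labels and species-tree reconciliation
are outside the model: only the topology and the coloring matter.

## Three routes to the least resolved tree

The package implements the three equivalent constructions and uses their
agreement as a standing cross-check:

1. **Neighborhood hierarchy** (`two_color`).  Thinness classes (vertices
   with equal out- and in-neighborhoods) are tested against the axioms
   N1–N3; when they hold, the extended reachable sets
   `R'(α) = R(α) ∪ Q(α)` form a hierarchy whose Hasse tree, with class
   members attached at `R'(α)`, is the LRT.  `R(α)` is computed by plain
   directed traversal (the definition), not via the two-step shortcut
   `N(α) ∪ N(N(α))` that is only valid under N2; a test asserts the two
   coincide on recognized graphs.
2. **Informative triples + BUILD** (`triples_build`).  The unified rule —
   `ab|c` whenever `σ(b) = σ(c) ≠ σ(a)`, arc `(a,b)` present, arc `(a,c)`
   absent — is used in production; an explicit matcher for the four
   induced patterns X1–X4 exists solely for cross-validation, and the
   test suite asserts their equality exhaustively on all properly
   2-colored 3-vertex digraphs.  Consistency of the informative triples
   is necessary but not sufficient, so recognition always re-verifies by
   regenerating the graph from the Aho tree.  BUILD is the plain
   recursive algorithm with the Aho graph recomputed per level; the
   asymptotically faster variants from the supertree literature are
   deliberately not used — correctness and auditability first.
3. **Redundant-edge contraction** (`bmg`).  For any tree explaining `G`,
   an inner edge `uv` is redundant iff no color occurring above `v`
   (in `L(T(u)) \ L(T(v))`) has a thinness class rooted at `v`; the class
   roots `ρ_{α,s}` are computed directly from the definition as a
   depth-minimal pairwise lca.  Contraction of all redundant edges in any
   order yields the LRT, and `lrt_by_contraction` verifies its own
   postcondition (regenerate and compare) because "the tree explains G"
   cannot be checked cheaply up front.

Multi-colored graphs are recognized per weak component (components must
share the same color set) by recognizing every induced two-color subgraph
and running BUILD on the union of the pairwise triples.  Two collections
are offered: the informative triples of the pairwise subgraphs (default
mode `"triples"`, the smaller set) or the full triple sets of the pairwise
LRTs (mode `"lrt"`); on genuine best match graphs both yield the same Aho
tree, which the tests assert.  Negative answers always carry a
certificate: the violated sanity condition, the failing axiom with a
witness class pair, a non-laminar set pair, the offending color pair, an
inconsistency witness subset, or a final regenerate-and-compare mismatch.

## Determinism and canonical forms

All constructions are deterministic set operations; iteration is fixed by
sorting (classes by smallest member, BUILD components by smallest leaf,
children by smallest subtended leaf label).  Tree equality is canonical
Newick string equality with `label|color` leaves, so LRT uniqueness is
tested as string identity.  Inner-vertex ids are implementation-internal;
edges are addressed as `(parent, child)` pairs valid only for the tree
snapshot they came from.

Degenerate inputs: a Newick root with a single child is suppressed with a
warning (single-leaf trees are allowed but flagged); a one-colored graph
is explained by every tree and its BMG is edge-less; a two-colored vertex
with no out-arc is rejected before the axiom machinery runs.

## Synthetic data

`fixtures.random_colored_tree` grows a random binary topology by uniform
edge subdivision, contracts each inner edge with probability
`1 − binary_prob`, and colors leaves surjectively (each species keeps at
least one gene, the rest drawn uniformly).  Defaults: `binary_prob = 0.8`,
giving mostly resolved trees with occasional polytomies — the regime
observable gene trees occupy after unresolvable duplications are
collapsed.  The generator emulates topology and species assignment only;
it does not model sequence noise, rate variation or horizontal transfer,
so passing tests certify the combinatorial theory, not robustness of best
match *estimation* from real similarity data.

Problem sizes used by the test suite are desk scale by design: the
round-trip battery uses 200 random trees with 2–40 leaves and 2–6 colors,
the invariant battery 100 instances per property at ≤ 14 leaves, and the
oracle sweep all sane 2-colored digraphs on ≤ 4 vertices plus 500 random
5-vertex instances.

## Exhaustive oracles

`enumerate_topologies` generates every rooted phylogenetic tree on a
small leaf set exactly once via set partitions at the root (1, 4, 26,
236, 2752 trees for 2–6 leaves; capped at 6).  `brute_force_is_cbmg`
decides membership by exhaustion, deriving arcs from per-topology
lca-depth tables — an arc computation independent of the library's
forward map, so oracle agreement is a genuine dual-route check.  The
minimal-counterexample search enumerates all weakly connected, properly
two-colored, out-complete digraphs by increasing vertex count (color
assignments up to swapping the two color names, which membership is
invariant under) and certifies the first non-member exhaustively.  No
graph is asserted non-explainable anywhere in the package without such a
certificate.

## Known limitations

* Complexity targets from the recognition theory (cubic time, quadratic
  space, constant-time lca) are treated as design guidance; the
  implementation favors the definitional formulas at `O(|L|²)`–`O(|L|³)`
  Python cost, which is ample at desk scale.
* The reciprocal (symmetric) layer implements only the necessary
  condition — every two-colored component of the symmetric part must be
  complete bipartite — plus extraction; full recognition of reciprocal
  best match graphs is out of scope.
* Recognition with an unknown coloring, and editing a near-miss graph to
  the closest best match graph, are not attempted.
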