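"""Informative triples, the Aho graph, and BUILD.

Certain three-vertex induced subgraphs of a two-colored digraph can only
arise from one rooted triple in any explaining tree.  The unified rule:
``ab|c`` is informative whenever ``sigma(b) = sigma(c) != sigma(a)``, the
arc ``(a, b)`` is present and the arc ``(a, c)`` is absent — then
``lca(a, b) < lca(a, c)`` is forced.  This is equivalent to matching the
four induced patterns X1–X4 (an explicit pattern matcher is kept alongside
and the equivalence is asserted in the test suite).

BUILD (Aho et al.) reconstructs a tree from a triple set ``R`` by
recursive decomposition of the Aho graph ``[R, L']``: vertices ``L'``,
edges ``{x, y}`` for triples ``xy|z`` with ``z`` inside ``L'``.  ``R`` is
consistent iff every recursion level decomposes into at least two
components.  Consistency of the informative triples is necessary but *not*
sufficient for a graph to be a best match graph; recognition therefore
always re-verifies by regenerating the graph from the Aho tree.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, List, Mapping, Optional, Set, Tuple

import networkx as nx

from .bmg import bmg_from_tree
from .digraphs import ColoredDigraph, color_sanity
from .trees import LeafColoredTree, Triple, TripleSet
from .two_color import RecognitionResult, _fail

__all__ = [
    "informative_triples",
    "x_pattern_triples",
    "component_triples",
    "combined_triples",
    "aho_graph",
    "BuildResult",
    "build_tree",
    "recognize_via_triples",
]


def informative_triples(G: ColoredDigraph) -> TripleSet:
    """All informative triples of a (at most) two-colored digraph."""
    if len(G.colors) > 2:
        raise ValueError("informative triples are defined per color pair; slice first")
    color_class = G.color_classes()
    out: Set[Triple] = set()
    for a in G.vertices:
        nb = G.out_neighbors(a)
        for b in nb:
            others = color_class[G.color_of(b)] - nb - {a}
            out.update(Triple.of(a, b, c) for c in others)
    return TripleSet(out, G.vertices)


def x_pattern_triples(G: ColoredDigraph) -> TripleSet:
    """Explicit matcher for the induced patterns X1–X4 (up to recoloring).

    X1: a<->b, c isolated, sigma(c) arbitrary;
    X2: a<->b, c->a, sigma(c) = sigma(b);
    X3: a->b,  c isolated, sigma(c) = sigma(b);
    X4: a->b,  c->a, sigma(c) = sigma(b).
    Each yields ``ab|c``.  Exists for cross-checking the unified rule.
    """
    out: Set[Triple] = set()
    for trio in itertools.combinations(sorted(G.vertices), 3):
        induced = {
            (x, y) for x, y in itertools.permutations(trio, 2) if G.has_arc(x, y)
        }
        for a, b, c in itertools.permutations(trio):
            if G.color_of(a) == G.color_of(b):
                continue
            same_bc = G.color_of(c) == G.color_of(b)
            if induced == {(a, b), (b, a)} and (same_bc or G.color_of(c) == G.color_of(a)):
                out.add(Triple.of(a, b, c))  # X1
            elif induced == {(a, b), (b, a), (c, a)} and same_bc:
                out.add(Triple.of(a, b, c))  # X2
            elif induced == {(a, b)} and same_bc:
                out.add(Triple.of(a, b, c))  # X3
            elif induced == {(a, b), (c, a)} and same_bc:
                out.add(Triple.of(a, b, c))  # X4
    return TripleSet(out, G.vertices)


def component_triples(G: ColoredDigraph) -> TripleSet:
    """All ``xy|z`` with x, y in one weak component and z in another."""
    comps = G.weak_components()
    out: Set[Triple] = set()
    for i, comp in enumerate(comps):
        inside = sorted(comp)
        outside = [v for j, c in enumerate(comps) if j != i for v in c]
        for x, y in itertools.combinations(inside, 2):
            out.update(Triple.of(x, y, z) for z in outside)
    return TripleSet(out, G.vertices)


def combined_triples(G: ColoredDigraph) -> TripleSet:
    """Informative triples per component, plus the component-separating ones."""
    acc = TripleSet((), G.vertices)
    for comp in G.weak_components():
        acc = acc | informative_triples(G.induced(comp))
    return acc | component_triples(G)


# ---------------------------------------------------------------------------
# BUILD


def aho_graph(R: TripleSet, subset: Iterable[str]) -> nx.Graph:
    """The Aho graph [R, L']: edges {x,y} for triples xy|z with z in L'."""
    keep = frozenset(subset)
    g = nx.Graph()
    g.add_nodes_from(keep)
    for t in R:
        if t.leaves() <= keep:
            g.add_edge(*t.pair)
    return g


@dataclass(frozen=True)
class BuildResult:
    tree: Optional[LeafColoredTree]
    witness: Optional[FrozenSet[str]]  # connected subset certifying inconsistency

    @property
    def consistent(self) -> bool:
        return self.tree is not None


def build_tree(
    R: TripleSet,
    leaves: Iterable[str],
    colors: Optional[Mapping[str, str]] = None,
) -> BuildResult:
    """The Aho tree of ``R`` over ``leaves``, or an inconsistency witness.

    Deterministic: recursion components are ordered by smallest leaf.
    Without a color table every leaf gets the placeholder color "0".
    """
    universe = frozenset(leaves)
    stray = R.leaf_universe - universe
    if stray:
        raise ValueError(f"triples mention leaves outside L: {sorted(stray)}")
    color_of = dict(colors) if colors is not None else {lf: "0" for lf in universe}

    class _Inconsistent(Exception):
        pass

    witness: List[FrozenSet[str]] = []
    children: Dict[object, List[object]] = {}
    counter = itertools.count()

    def recurse(subset: FrozenSet[str]) -> object:
        if len(subset) == 1:
            (lf,) = subset
            children[lf] = []
            return lf
        comps = sorted(
            (frozenset(c) for c in nx.connected_components(aho_graph(R, subset))),
            key=min,
        )
        if len(comps) == 1:
            witness.append(subset)
            raise _Inconsistent
        vid = next(counter)
        children[vid] = [recurse(c) for c in comps]
        return vid

    try:
        root = recurse(universe)
    except _Inconsistent:
        return BuildResult(None, witness[0])
    return BuildResult(LeafColoredTree(children, root, color_of), None)


# ---------------------------------------------------------------------------
# Recognition via triples


def recognize_via_triples(G: ColoredDigraph) -> RecognitionResult:
    """Triple-route recognition of a two-colored digraph.

    Computes the informative triples (augmented with component-separating
    triples when the graph is disconnected), builds the Aho tree, and
    accepts iff the tree regenerates exactly the input graph.
    """
    if len(G.colors) != 2:
        return _fail("precheck", f"expected 2 colors, found {len(G.colors)}")
    same = [v for v in color_sanity(G) if v[0] == "same_color_arc"]
    if same:
        return _fail("sanity", "arc inside a color class", witness=same[0])
    R = combined_triples(G)
    built = build_tree(R, G.vertices, G.color_map())
    if not built.consistent:
        return _fail(
            "inconsistent",
            "informative triples are inconsistent",
            witness_vertices=tuple(sorted(built.witness)),
        )
    if bmg_from_tree(built.tree) != G:
        return _fail("verification", "Aho tree does not regenerate the graph")
    return RecognitionResult(True, built.tree, None)
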