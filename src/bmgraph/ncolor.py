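"""Recognition of best match graphs with arbitrarily many colors.

An ``n``-colored digraph is a best match graph iff (i) every induced
subgraph on two colors is a two-colored best match graph and (ii) the
union of the triples contributed by the color pairs is consistent; the
Aho tree of that union is then the unique least resolved tree.  Two
equivalent triple collections can be used: the full triple sets of the
pairwise least resolved trees (mode ``"lrt"``) or just the informative
triples of the pairwise subgraphs (mode ``"triples"``); both yield the
same Aho tree on actual best match graphs, which the test suite asserts.

The reciprocal layer keeps only bidirectional arcs.  Restricted to two
colors, a reciprocal best match graph is a disjoint union of complete
bipartite graphs — a necessary (not sufficient) condition checked by
:func:`rbmg_bipartite_check`.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, List, Optional, Tuple

from .bmg import bmg_from_tree, lrt_by_contraction
from .digraphs import ColoredDigraph, ColoredGraph
from .trees import LeafColoredTree, TripleSet, tree_triples
from .triples_build import build_tree, combined_triples
from .two_color import (
    RecognitionResult,
    _fail,
    join_under_root,
    recognize_2cbmg,
)

__all__ = [
    "PairwiseDecomposition",
    "recognize_ncbmg",
    "lrt_ncolor",
    "rbmg_bipartite_check",
]


@dataclass
class PairwiseDecomposition:
    """Per-color-pair slicing of a connected multi-colored digraph."""

    color_pairs: List[Tuple[str, str]] = field(default_factory=list)
    sub_bmgs: Dict[Tuple[str, str], ColoredDigraph] = field(default_factory=dict)
    sub_lrts: Dict[Tuple[str, str], LeafColoredTree] = field(default_factory=dict)
    triple_union: Optional[TripleSet] = None


def _recognize_component(G: ColoredDigraph, mode: str):
    """Recognition of one weak component; returns (result, decomposition)."""
    decomp = PairwiseDecomposition()
    triples = TripleSet((), G.vertices)
    for s, t in itertools.combinations(sorted(G.colors), 2):
        sub = G.induced_by_colors({s, t})
        decomp.color_pairs.append((s, t))
        decomp.sub_bmgs[(s, t)] = sub
        res = recognize_2cbmg(sub)
        if not res.is_bmg:
            cert = dict(res.certificate)
            cert["color_pair"] = (s, t)
            return RecognitionResult(False, None, cert), decomp
        decomp.sub_lrts[(s, t)] = res.lrt
        if mode == "lrt":
            triples = triples | tree_triples(res.lrt)
        else:
            triples = triples | combined_triples(sub)
    decomp.triple_union = triples
    built = build_tree(triples, G.vertices, G.color_map())
    if not built.consistent:
        return (
            _fail(
                "inconsistent",
                "pairwise triples are jointly inconsistent",
                witness_vertices=tuple(sorted(built.witness)),
            ),
            decomp,
        )
    if bmg_from_tree(built.tree) != G:
        return _fail("verification", "Aho tree does not regenerate the graph"), decomp
    return RecognitionResult(True, built.tree, None), decomp


def recognize_ncbmg(G: ColoredDigraph, mode: str = "triples") -> RecognitionResult:
    """Decide whether a colored digraph is a best match graph; return its LRT.

    ``mode="triples"`` collects the informative triples of the two-color
    induced subgraphs (the smaller set); ``mode="lrt"`` collects all
    triples of the pairwise least resolved trees.  Weak components must
    share a common color set; the global least resolved tree joins the
    component trees under a fresh root.
    """
    if mode not in ("triples", "lrt"):
        raise ValueError(f"unknown mode {mode!r}")
    if len(G.colors) < 2:
        return _fail("precheck", "need at least 2 colors")
    comps = G.weak_components()
    if len(comps) > 1:
        want = G.colors
        for comp in comps:
            if {G.color_of(v) for v in comp} != want:
                return _fail(
                    "components",
                    "connected component misses a color",
                    witness_vertices=tuple(sorted(comp)),
                )
    lrts = []
    for comp in comps:
        res, _ = _recognize_component(G.induced(comp), mode)
        if not res.is_bmg:
            cert = dict(res.certificate)
            cert.setdefault("component", tuple(sorted(comp)))
            return RecognitionResult(False, None, cert)
        lrts.append(res.lrt)
    return RecognitionResult(True, join_under_root(lrts), None)


def lrt_ncolor(tree: LeafColoredTree) -> LeafColoredTree:
    """Least resolved tree of the graph explained by ``tree`` (contraction route)."""
    return lrt_by_contraction(tree, bmg_from_tree(tree))


def rbmg_bipartite_check(
    G_sym: ColoredGraph, pair: Optional[Tuple[str, str]] = None
) -> Tuple[bool, Optional[Dict]]:
    """Necessary condition for a two-colored reciprocal best match graph.

    Every connected component with at least two vertices must be complete
    bipartite across the two color classes.  Returns ``(ok, witness)``
    where the witness names the offending component and defect.
    """
    g = G_sym if pair is None else G_sym.induced_by_colors(pair)
    cols = sorted(g.colors)
    if len(cols) > 2:
        raise ValueError("restrict to two colors first")
    for comp in g.components():
        if len(comp) < 2:
            continue
        sides: Dict[str, set] = {}
        for v in comp:
            sides.setdefault(g.color_of(v), set()).add(v)
        if len(sides) != 2:
            return False, {"component": tuple(sorted(comp)), "defect": "monochromatic"}
        a, b = sides.values()
        for x in a:
            missing = b - g.neighbors(x)
            if missing:
                return False, {
                    "component": tuple(sorted(comp)),
                    "defect": "missing_edge",
                    "witness_vertices": (x, min(missing)),
                }
        for x, y in itertools.combinations(sorted(comp), 2):
            if frozenset((x, y)) in g.edges and g.color_of(x) == g.color_of(y):
                return False, {
                    "component": tuple(sorted(comp)),
                    "defect": "same_color_edge",
                    "witness_vertices": (x, y),
                }
    return True, None
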