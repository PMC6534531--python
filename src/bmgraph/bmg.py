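"""From trees to best match graphs, and back by edge contraction.

``bmg_from_tree`` is the forward map: the arc ``x -> y`` is present iff
``sigma(x) != sigma(y)`` and ``lca(x, y) <= lca(x, y')`` for every ``y'``
of ``y``'s color.  Because the ancestors of ``x`` are totally ordered, the
best matches of ``x`` in color ``s`` are exactly the ``s``-leaves below the
lowest ancestor of ``x`` whose subtree contains color ``s`` at all; the
whole graph is built in quadratic time.

Going back, many trees explain the same graph.  An inner edge ``uv`` is
*redundant* when contracting it leaves the explained graph unchanged;
that happens exactly when ``v`` is not the color-``s`` root of any thinness
class for any color ``s`` occurring in ``L(T(u)) \\ L(T(v))``.  Contracting
all redundant edges (in any order) of any explaining tree yields the unique
*least resolved tree* (LRT) of the graph.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Optional, Set, Tuple

from .digraphs import ColoredDigraph, ThinnessPartition, thinness_partition
from .trees import LeafColoredTree

__all__ = [
    "ExplanationError",
    "ClassRoots",
    "bmg_from_tree",
    "class_roots",
    "redundant_edges",
    "lrt_by_contraction",
]


class ExplanationError(ValueError):
    """The supplied tree does not explain the supplied graph."""


def bmg_from_tree(tree: LeafColoredTree) -> ColoredDigraph:
    """The colored best match graph explained by ``tree``.

    For a single color the graph is edge-less (any tree explains it).
    """
    colors = tree.color_set
    # per-vertex count of leaves of each color in the subtree
    color_count: Dict[object, Dict[str, int]] = {}
    order = [tree.root]
    for v in order:
        order.extend(tree.children[v])
    for v in reversed(order):
        if tree.is_leaf(v):
            color_count[v] = {tree.color_of[v]: 1}
        else:
            acc: Dict[str, int] = {}
            for c in tree.children[v]:
                for s, n in color_count[c].items():
                    acc[s] = acc.get(s, 0) + n
            color_count[v] = acc

    color_class = tree.color_classes()
    arcs = []
    for x in tree.leaves:
        for s in colors:
            if s == tree.color_of[x]:
                continue
            for v in tree.ancestors(x):
                if color_count[v].get(s, 0):
                    arcs.extend((x, y) for y in tree.subtree_leaves(v) & color_class[s])
                    break
    return ColoredDigraph(tree.color_of, arcs)


@dataclass(frozen=True)
class ClassRoots:
    """Roots of thinness classes inside an explaining tree.

    ``root_per_color[(alpha, s)]`` is the highest lca between a member of
    class ``alpha`` and one of its color-``s`` out-neighbors.  The subtree
    at that vertex contains exactly the color-``s`` out-neighborhood of the
    class among its ``s``-leaves.
    """

    root_per_color: Dict[Tuple[str, str], object]

    def root_of(self, class_id: str) -> object:
        """The unique class root in the 2-color case."""
        roots = {v for (a, _s), v in self.root_per_color.items() if a == class_id}
        if len(roots) != 1:
            raise ValueError(
                f"class {class_id!r} has {len(roots)} per-color roots; "
                "root_of is only defined for two-colored graphs"
            )
        return next(iter(roots))


def class_roots(
    tree: LeafColoredTree,
    G: Optional[ColoredDigraph] = None,
    partition: Optional[ThinnessPartition] = None,
) -> ClassRoots:
    """Compute ``rho_{alpha,s}`` for every class and every color ``s != sigma(alpha)``.

    ``tree`` must explain ``G`` (the caller's responsibility; downstream
    consumers re-verify).  Computed directly as the depth-minimal pairwise
    lca between class members and their color-``s`` out-neighbors.
    """
    if G is None:
        G = bmg_from_tree(tree)
    if partition is None:
        partition = thinness_partition(G)
    out: Dict[Tuple[str, str], object] = {}
    for cid in partition.class_ids:
        nbhd = G.out_neighbors(cid)  # class-constant, any member works
        by_color: Dict[str, Set[str]] = {}
        for y in nbhd:
            by_color.setdefault(G.color_of(y), set()).add(y)
        for s, ys in by_color.items():
            best = None
            for x in partition.members[cid]:
                for y in ys:
                    a = tree.lca((x, y))
                    if best is None or tree.depth[a] < tree.depth[best]:
                        best = a
            out[(cid, s)] = best
    return ClassRoots(out)


def redundant_edges(
    tree: LeafColoredTree, G: Optional[ColoredDigraph] = None
) -> FrozenSet[Tuple[object, object]]:
    """All redundant inner edges of ``tree`` with respect to ``G``.

    ``uv`` is redundant iff it is inner and no color ``s`` occurring in
    ``L(T(u)) \\ L(T(v))`` has a thinness class whose color-``s`` root is
    ``v``.
    """
    if G is None:
        G = bmg_from_tree(tree)
    roots = class_roots(tree, G)
    colors_rooted_at: Dict[object, Set[str]] = {}
    for (_cid, s), v in roots.root_per_color.items():
        colors_rooted_at.setdefault(v, set()).add(s)
    out = []
    for u, v in tree.inner_edges():
        above = tree.subtree_leaves(u) - tree.subtree_leaves(v)
        colors_above = {tree.color_of[lf] for lf in above}
        if not (colors_rooted_at.get(v, set()) & colors_above):
            out.append((u, v))
    return frozenset(out)


def lrt_by_contraction(
    tree: LeafColoredTree, G: Optional[ColoredDigraph] = None
) -> LeafColoredTree:
    """The least resolved tree of ``G``, by contracting all redundant edges.

    Verifies its own postcondition (the contracted tree must still explain
    ``G`` and admit no further contraction); a failure means ``tree`` did
    not explain ``G`` in the first place.
    """
    if G is None:
        G = bmg_from_tree(tree)
    lrt = tree.contract_edges(redundant_edges(tree, G))
    if bmg_from_tree(lrt) != G:
        raise ExplanationError(
            "contracted tree does not explain the graph; "
            "the input tree did not explain it"
        )
    if redundant_edges(lrt, G):
        raise ExplanationError("redundant edges remain after contraction")
    return lrt
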