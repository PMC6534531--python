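"""Recognition of two-colored best match graphs.

A connected two-colored digraph is a best match graph iff its thinness
classes satisfy three neighborhood axioms:

* (N1) if two classes are not in each other's out-neighborhood, their
  out-neighborhoods are disjoint from each other's second neighborhoods;
* (N2) ``N(N(N(alpha))) ⊆ N(alpha)``;
* (N3) if two classes are outside each other's second neighborhoods but
  their out-neighborhoods overlap, then they share their in-neighborhood
  and their out-neighborhoods are nested.

When the axioms hold, the *extended reachable sets* ``R'(alpha) =
R(alpha) ∪ Q(alpha)`` — directed reachability plus the auxiliary set of
classes with the same in-neighborhood and nested out-neighborhood — form a
hierarchy on the vertex set.  The Hasse tree of that hierarchy, with the
members of each class attached at ``R'(alpha)``, is the unique least
resolved tree explaining the graph.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Dict, FrozenSet, List, Optional, Set, Tuple

from .bmg import bmg_from_tree
from .digraphs import (
    ColoredDigraph,
    ThinnessPartition,
    color_sanity,
    thinness_partition,
)
from .trees import LeafColoredTree, TreeError

__all__ = [
    "AxiomReport",
    "SinkReport",
    "Hierarchy",
    "HierarchyResult",
    "RecognitionResult",
    "check_axioms",
    "sink_classes",
    "reachable_set",
    "q_set",
    "extended_reachable_set",
    "hierarchy_of_extended_sets",
    "lrt_from_hierarchy",
    "recognize_2cbmg",
    "join_under_root",
]


# ---------------------------------------------------------------------------
# Results


@dataclass(frozen=True)
class AxiomReport:
    n1: bool
    n2: bool
    n3: bool
    witnesses: Dict[str, Tuple[str, ...]]

    @property
    def all_hold(self) -> bool:
        return self.n1 and self.n2 and self.n3


@dataclass(frozen=True)
class SinkReport:
    """Structure over the classes without in-neighbors (the set W)."""

    sinks: Tuple[str, ...]
    case: str  # "empty" | "single" | "multiple"
    alpha_star: Optional[str]
    consistent: bool  # whether the expected reachability trichotomy holds


@dataclass(frozen=True)
class Hierarchy:
    """A laminar family of leaf subsets containing the full leaf set."""

    sets: FrozenSet[FrozenSet[str]]
    universe: FrozenSet[str]

    def is_laminar(self) -> Optional[Tuple[FrozenSet[str], FrozenSet[str]]]:
        """None if laminar; otherwise a properly overlapping pair."""
        sets = sorted(self.sets, key=lambda s: (-len(s), sorted(s)))
        for a, b in itertools.combinations(sets, 2):
            if a & b and not (a <= b or b <= a):
                return (a, b)
        return None


@dataclass(frozen=True)
class HierarchyResult:
    hierarchy: Optional[Hierarchy]
    overlap: Optional[Tuple[FrozenSet[str], FrozenSet[str]]]

    @property
    def ok(self) -> bool:
        return self.hierarchy is not None


@dataclass(frozen=True)
class RecognitionResult:
    is_bmg: bool
    lrt: Optional[LeafColoredTree]
    certificate: Optional[Dict]

    def __bool__(self) -> bool:
        return self.is_bmg


# ---------------------------------------------------------------------------
# Class-level neighborhood calculus

def _out1(P: ThinnessPartition, a: str) -> FrozenSet[str]:
    return P.out_nbhd[a]


def _out2(P: ThinnessPartition, a: str) -> FrozenSet[str]:
    return frozenset(itertools.chain.from_iterable(P.out_nbhd[b] for b in P.out_nbhd[a]))


def _out3(P: ThinnessPartition, a: str) -> FrozenSet[str]:
    return frozenset(itertools.chain.from_iterable(P.out_nbhd[b] for b in _out2(P, a)))


def check_axioms(G: ColoredDigraph, P: Optional[ThinnessPartition] = None) -> AxiomReport:
    """Evaluate the three neighborhood axioms on the class quotient.

    Intended for weakly connected two-colored graphs whose vertices all
    have an out-neighbor of the opposite color; the first failing class
    pair for each axiom is recorded as a witness.
    """
    if len(G.colors) != 2:
        raise ValueError(f"expected exactly 2 colors, got {len(G.colors)}")
    if P is None:
        P = thinness_partition(G)
    ids = P.class_ids
    out2 = {a: _out2(P, a) for a in ids}
    witnesses: Dict[str, Tuple[str, ...]] = {}

    n1 = True
    for a, b in itertools.combinations(ids, 2):
        if a not in _out1(P, b) and b not in _out1(P, a):
            if _out1(P, a) & out2[b] or _out1(P, b) & out2[a]:
                n1, witnesses["N1"] = False, (a, b)
                break

    n2 = True
    for a in ids:
        if not _out3(P, a) <= _out1(P, a):
            n2, witnesses["N2"] = False, (a,)
            break

    n3 = True
    for a, b in itertools.combinations(ids, 2):
        if a not in out2[b] and b not in out2[a] and _out1(P, a) & _out1(P, b):
            nested = _out1(P, a) <= _out1(P, b) or _out1(P, b) <= _out1(P, a)
            if P.in_nbhd[a] != P.in_nbhd[b] or not nested:
                n3, witnesses["N3"] = False, (a, b)
                break

    return AxiomReport(n1, n2, n3, witnesses)


def reachable_set(
    G: ColoredDigraph, P: ThinnessPartition, class_id: str
) -> FrozenSet[str]:
    """All vertices reachable from class ``class_id`` along directed arcs.

    Computed by plain traversal on the class quotient; equals
    ``N(alpha) ∪ N(N(alpha))`` whenever (N2) holds.
    """
    if class_id not in P.members:
        raise KeyError(f"unknown class {class_id!r}")
    seen: Set[str] = set()
    frontier = set(P.out_nbhd[class_id])
    while frontier:
        seen |= frontier
        frontier = set(
            itertools.chain.from_iterable(P.out_nbhd[b] for b in frontier)
        ) - seen
    return P.vertices_of(seen)


def q_set(P: ThinnessPartition, class_id: str) -> FrozenSet[str]:
    """Union of classes with the same in-neighborhood and nested out-neighborhood."""
    a = class_id
    ids = [
        b
        for b in P.class_ids
        if P.in_nbhd[b] == P.in_nbhd[a] and P.out_nbhd[b] <= P.out_nbhd[a]
    ]
    return P.vertices_of(ids)


def extended_reachable_set(
    G: ColoredDigraph, P: ThinnessPartition, class_id: str
) -> FrozenSet[str]:
    return reachable_set(G, P, class_id) | q_set(P, class_id)


def sink_classes(G: ColoredDigraph, P: Optional[ThinnessPartition] = None) -> SinkReport:
    """Diagnostic structure over the in-neighbor-free classes.

    For a connected two-colored best match graph exactly one of three
    situations holds: no sink class (two classes share the tree root), a
    single sink class whose reachable set is everything else, or several
    sink classes among which a unique one reaches all non-sink vertices.
    """
    if P is None:
        P = thinness_partition(G)
    W = P.sinks
    sink_vertices = P.vertices_of(W)
    if not W:
        return SinkReport(W, "empty", None, True)
    if len(W) == 1:
        (a,) = W
        ok = reachable_set(G, P, a) == G.vertices - P.members[a]
        return SinkReport(W, "single", a, ok)
    target = G.vertices - sink_vertices
    stars = [a for a in W if reachable_set(G, P, a) == target]
    return SinkReport(W, "multiple", stars[0] if len(stars) == 1 else None, len(stars) == 1)


# ---------------------------------------------------------------------------
# Hierarchy and the least resolved tree


def hierarchy_of_extended_sets(
    G: ColoredDigraph, P: Optional[ThinnessPartition] = None
) -> HierarchyResult:
    """Collect ``{R'(alpha)}`` and check it is a hierarchy on the vertex set."""
    if P is None:
        P = thinness_partition(G)
    sets = frozenset(extended_reachable_set(G, P, a) for a in P.class_ids)
    hier = Hierarchy(sets, G.vertices)
    overlap = hier.is_laminar()
    if overlap is not None:
        return HierarchyResult(None, overlap)
    if G.vertices not in sets:
        # no maximal element covering everything: not a hierarchy on L
        biggest = max(sets, key=len, default=frozenset())
        return HierarchyResult(None, (biggest, G.vertices))
    return HierarchyResult(hier, None)


def lrt_from_hierarchy(
    G: ColoredDigraph, P: ThinnessPartition, H: Hierarchy
) -> LeafColoredTree:
    """Hasse tree of the hierarchy with class members attached at ``R'(alpha)``.

    Raises :class:`TreeError` if the construction is not phylogenetic,
    which cannot happen when ``H`` really is the extended-reachable-set
    hierarchy of a best match graph.
    """
    sets = sorted(H.sets, key=lambda s: (-len(s), sorted(s)))
    node_of = {s: i for i, s in enumerate(sets)}
    children: Dict[object, List[object]] = {i: [] for i in node_of.values()}
    for i, s in enumerate(sets):
        # parent = smallest strict superset (sets precede their subsets)
        parent = None
        for j in range(i - 1, -1, -1):
            if s < sets[j]:
                parent = node_of[sets[j]]
                break
        if parent is not None:
            children[parent].append(node_of[s])
    for a in P.class_ids:
        rp = extended_reachable_set(G, P, a)
        if rp not in node_of:
            raise TreeError(f"extended reachable set of class {a!r} missing from hierarchy")
        children[node_of[rp]].extend(sorted(P.members[a]))
    for lf in G.vertices:
        children.setdefault(lf, [])
    root = node_of[max(sets, key=len)]
    return LeafColoredTree(children, root, G.color_map())


# ---------------------------------------------------------------------------
# Recognition


def join_under_root(trees: List[LeafColoredTree]) -> LeafColoredTree:
    """Join component trees as children of a fresh root."""
    if len(trees) == 1:
        return trees[0]
    colors: Dict[str, str] = {}
    for t in trees:
        colors.update(t.color_of)
    nested = tuple(t.to_nested() for t in trees)
    return LeafColoredTree.from_nested(nested, colors)


def _fail(stage: str, message: str, **extra) -> RecognitionResult:
    return RecognitionResult(False, None, {"stage": stage, "message": message, **extra})


def _recognize_connected_2cbmg(G: ColoredDigraph) -> RecognitionResult:
    violations = color_sanity(G, require_out=True)
    if violations:
        return _fail("sanity", "necessary out-neighbor/color condition violated",
                     witness=violations[0])
    P = thinness_partition(G)
    report = check_axioms(G, P)
    if not report.all_hold:
        axiom = next(iter(report.witnesses))
        return _fail("axioms", f"axiom {axiom} fails",
                     witness_vertices=report.witnesses[axiom])
    hres = hierarchy_of_extended_sets(G, P)
    if not hres.ok:
        return _fail("hierarchy", "extended reachable sets are not laminar",
                     witness=tuple(sorted(map(sorted, hres.overlap))))
    try:
        lrt = lrt_from_hierarchy(G, P, hres.hierarchy)
    except TreeError as exc:
        return _fail("hierarchy_tree", str(exc))
    if bmg_from_tree(lrt) != G:
        return _fail("verification", "hierarchy tree does not regenerate the graph")
    return RecognitionResult(True, lrt, None)


def recognize_2cbmg(G: ColoredDigraph) -> RecognitionResult:
    """Decide whether a two-colored digraph is a best match graph.

    Disconnected inputs are handled per weak component: every component
    must carry both colors (otherwise some vertex would have a best match
    in another component), and the global least resolved tree joins the
    component trees under a fresh root.
    """
    if len(G.colors) != 2:
        return _fail("precheck", f"expected 2 colors, found {len(G.colors)}")
    violations = color_sanity(G, require_out=True)
    if violations:
        return _fail("sanity", "necessary out-neighbor/color condition violated",
                     witness=violations[0])
    comps = G.weak_components()
    if len(comps) > 1:
        want = G.colors
        for comp in comps:
            have = {G.color_of(v) for v in comp}
            if have != want:
                return _fail(
                    "components",
                    "connected component misses a color",
                    witness_vertices=tuple(sorted(comp)),
                )
    lrts = []
    for comp in comps:
        res = _recognize_connected_2cbmg(G.induced(comp))
        if not res.is_bmg:
            cert = dict(res.certificate)
            cert.setdefault("component", tuple(sorted(comp)))
            return RecognitionResult(False, None, cert)
        lrts.append(res.lrt)
    return RecognitionResult(True, join_under_root(lrts), None)
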