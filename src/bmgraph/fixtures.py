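"""Synthetic instances and exhaustive oracles.

Random leaf-colored trees emulate observable gene trees: a random binary
topology grown by edge subdivision, partially unresolved by contracting
each inner edge with a fixed probability, and a surjective leaf coloring
(every species keeps at least one gene).  They carry no branch lengths or
event labels — recognition only consumes the topology and the coloring.

The oracles close the loop on every negative recognition answer at desk
scale: :func:`enumerate_topologies` generates every rooted phylogenetic
tree on a small leaf set exactly once (1, 4, 26, 236, 2752 trees for 2–6
leaves), and :func:`brute_force_is_cbmg` decides membership by exhaustion.
The brute-force arc computation works from per-topology lca-depth tables
and is deliberately independent of :func:`bmgraph.bmg.bmg_from_tree`.
"""

from __future__ import annotations

import itertools
import random
from dataclasses import dataclass
from functools import lru_cache
from typing import Dict, FrozenSet, Iterable, Iterator, List, Optional, Sequence, Tuple

from .digraphs import ColoredDigraph
from .trees import LeafColoredTree
from .triples_build import build_tree, informative_triples
from .bmg import bmg_from_tree

__all__ = [
    "RandomTreeSpec",
    "random_colored_tree",
    "random_colored_digraph",
    "enumerate_topologies",
    "enumerate_trees",
    "count_topologies",
    "brute_force_is_cbmg",
    "minimal_counterexample_search",
    "SearchResult",
    "consistent_but_unexplained_graph",
]

ENUMERATION_CAP = 6


# ---------------------------------------------------------------------------
# Random generation


@dataclass(frozen=True)
class RandomTreeSpec:
    """Parameters of the random leaf-colored tree generator.

    ``binary_prob`` is the probability that an inner edge of the grown
    binary topology is kept (rather than contracted into a polytomy);
    the default 0.8 yields mostly resolved trees with occasional
    multifurcations.
    """

    n_leaves: int
    n_colors: int
    binary_prob: float = 0.8
    seed: int = 0

    def __post_init__(self):
        if not 1 <= self.n_colors <= self.n_leaves:
            raise ValueError("need 1 <= n_colors <= n_leaves")
        if not 0.0 <= self.binary_prob <= 1.0:
            raise ValueError("binary_prob must be a probability")


def random_colored_tree(spec: RandomTreeSpec) -> LeafColoredTree:
    """A reproducible random phylogenetic tree with a surjective coloring."""
    rng = random.Random(spec.seed)
    n = spec.n_leaves
    labels = [f"g{i:02d}" for i in range(1, n + 1)]
    palette = [f"s{i}" for i in range(1, spec.n_colors + 1)]
    if n == 1:
        return LeafColoredTree({labels[0]: ()}, labels[0], {labels[0]: palette[0]})

    counter = itertools.count()
    root = next(counter)
    children: Dict[object, List[object]] = {root: labels[:2]}
    parent: Dict[object, object] = {labels[0]: root, labels[1]: root}
    edges: List[Tuple[object, object]] = [(root, labels[0]), (root, labels[1])]
    for lf in labels[2:]:
        u, v = edges[rng.randrange(len(edges))]
        w = next(counter)
        children[u][children[u].index(v)] = w
        children[w] = [v, lf]
        parent[v] = w
        parent[w] = u
        parent[lf] = w
        edges.remove((u, v))
        edges.extend([(u, w), (w, v), (w, lf)])
    # partial resolution: contract surviving inner edges with prob 1 - binary_prob
    tree = LeafColoredTree(children, root, dict.fromkeys(labels, palette[0]))
    drop = [e for e in tree.inner_edges() if rng.random() > spec.binary_prob]
    if drop:
        tree = tree.contract_edges(drop)

    shuffled = labels[:]
    rng.shuffle(shuffled)
    color_of = {lf: palette[i] for i, lf in enumerate(shuffled[: spec.n_colors])}
    for lf in shuffled[spec.n_colors:]:
        color_of[lf] = rng.choice(palette)
    return LeafColoredTree(tree.children, tree.root, color_of)


def random_colored_digraph(
    n: int,
    seed: int,
    n_colors: int = 2,
    require_sane: bool = True,
    max_attempts: int = 10_000,
) -> ColoredDigraph:
    """A random properly colored digraph; with ``require_sane``, weakly
    connected with every vertex having at least one out-arc.
    """
    rng = random.Random(seed)
    labels = [f"v{i}" for i in range(1, n + 1)]
    palette = [f"s{i}" for i in range(1, n_colors + 1)]
    for _ in range(max_attempts):
        colors = {lf: rng.choice(palette) for lf in labels}
        if len(set(colors.values())) != n_colors:
            continue
        candidates = [
            (x, y)
            for x in labels
            for y in labels
            if x != y and colors[x] != colors[y]
        ]
        arcs = [a for a in candidates if rng.random() < 0.5]
        G = ColoredDigraph(colors, arcs)
        if not require_sane:
            return G
        if all(G.out_neighbors(v) for v in labels) and G.is_connected():
            return G
    raise RuntimeError("failed to sample a sane digraph; widen max_attempts")


# ---------------------------------------------------------------------------
# Exhaustive enumeration


def _set_partitions(items: Tuple[str, ...]) -> Iterator[Tuple[Tuple[str, ...], ...]]:
    """All partitions of ``items`` into unordered blocks (blocks sorted by min)."""
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for part in _set_partitions(rest):
        yield ((first,),) + part
        for i, block in enumerate(part):
            yield part[:i] + ((first,) + block,) + part[i + 1 :]


@lru_cache(maxsize=None)
def _topologies(leaves: Tuple[str, ...]) -> Tuple[object, ...]:
    if len(leaves) == 1:
        return (leaves[0],)
    out = []
    for part in _set_partitions(leaves):
        if len(part) < 2:
            continue
        blocks = tuple(sorted(part, key=lambda b: min(b)))
        for combo in itertools.product(*(_topologies(tuple(sorted(b))) for b in blocks)):
            out.append(tuple(combo))
    return tuple(out)


def enumerate_topologies(leaves: Iterable[str], cap: int = ENUMERATION_CAP) -> Tuple[object, ...]:
    """Every rooted phylogenetic tree shape on ``leaves`` as nested tuples."""
    lv = tuple(sorted(leaves))
    if len(lv) > cap:
        raise ValueError(f"{len(lv)} leaves exceeds the enumeration cap {cap}")
    return _topologies(lv)


def count_topologies(n: int) -> int:
    return len(enumerate_topologies([f"l{i}" for i in range(n)]))


def enumerate_trees(
    leaves: Iterable[str], color_of: Dict[str, str], cap: int = ENUMERATION_CAP
) -> Iterator[LeafColoredTree]:
    for topo in enumerate_topologies(leaves, cap):
        yield LeafColoredTree.from_nested(topo, color_of)


# ---------------------------------------------------------------------------
# Brute-force membership


@lru_cache(maxsize=None)
def _lca_depth_tables(leaves: Tuple[str, ...]) -> Tuple[Tuple[object, Dict[Tuple[str, str], int]], ...]:
    """(topology, pairwise lca-depth table) for every topology on ``leaves``."""
    tables = []
    for topo in _topologies(leaves):
        depth: Dict[Tuple[str, str], int] = {}

        def walk(node: object, d: int) -> Tuple[str, ...]:
            if isinstance(node, str):
                return (node,)
            subs = [walk(c, d + 1) for c in node]
            for i, a in enumerate(subs):
                for b in subs[i + 1 :]:
                    for x in a:
                        for y in b:
                            depth[(x, y)] = depth[(y, x)] = d
            return tuple(itertools.chain.from_iterable(subs))

        walk(topo, 0)
        tables.append((topo, depth))
    return tuple(tables)


def _arcs_from_depths(
    depth: Dict[Tuple[str, str], int],
    color_of: Dict[str, str],
    color_class: Dict[str, FrozenSet[str]],
) -> FrozenSet[Tuple[str, str]]:
    arcs = []
    for x in color_of:
        for s, members in color_class.items():
            if s == color_of[x]:
                continue
            best = max(depth[(x, y)] for y in members)
            arcs.extend((x, y) for y in members if depth[(x, y)] == best)
    return frozenset(arcs)


def brute_force_is_cbmg(
    G: ColoredDigraph, cap: int = ENUMERATION_CAP
) -> Tuple[bool, Optional[LeafColoredTree]]:
    """Decide membership by trying every rooted phylogenetic tree on the
    vertex set; returns the first witness tree on success.
    """
    leaves = tuple(sorted(G.vertices))
    if len(leaves) > cap:
        raise ValueError(f"{len(leaves)} vertices exceeds the enumeration cap {cap}")
    color_of = G.color_map()
    color_class = G.color_classes()
    target = G.arcs
    for topo, depth in _lca_depth_tables(leaves):
        if _arcs_from_depths(depth, color_of, color_class) == target:
            return True, LeafColoredTree.from_nested(topo, color_of)
    return False, None


# ---------------------------------------------------------------------------
# Minimal counterexample


@dataclass(frozen=True)
class SearchResult:
    size: int
    example: ColoredDigraph
    candidates_checked: Dict[int, int]
    non_members: Dict[int, int]


def _sane_two_colored_candidates(n: int) -> Iterator[ColoredDigraph]:
    """All weakly connected, properly two-colored, out-complete digraphs on
    ``n`` vertices, up to swapping the two color names (vertex v1 is
    pinned to the first color).
    """
    labels = [f"v{i}" for i in range(1, n + 1)]
    for rest in itertools.product(("s1", "s2"), repeat=n - 1):
        colors = dict(zip(labels, ("s1",) + rest))
        if len(set(colors.values())) != 2:
            continue
        candidate_arcs = [
            (x, y) for x in labels for y in labels if x != y and colors[x] != colors[y]
        ]
        for mask in itertools.product((False, True), repeat=len(candidate_arcs)):
            arcs = [a for a, keep in zip(candidate_arcs, mask) if keep]
            G = ColoredDigraph(colors, arcs)
            if not all(G.out_neighbors(v) for v in labels):
                continue
            if not G.is_connected():
                continue
            yield G


def minimal_counterexample_search(max_n: int = 4) -> SearchResult:
    """Smallest vertex count admitting a sane two-colored digraph that no
    tree explains, certified by exhaustive tree enumeration.
    """
    checked: Dict[int, int] = {}
    bad: Dict[int, int] = {}
    first_example: Optional[ColoredDigraph] = None
    first_size: Optional[int] = None
    for n in range(2, max_n + 1):
        checked[n] = 0
        bad[n] = 0
        for G in _sane_two_colored_candidates(n):
            checked[n] += 1
            ok, _ = brute_force_is_cbmg(G)
            if not ok:
                bad[n] += 1
                if first_example is None:
                    first_example, first_size = G, n
        if first_example is not None:
            break
    if first_example is None:
        raise RuntimeError(f"no counterexample up to {max_n} vertices")
    return SearchResult(first_size, first_example, checked, bad)


# ---------------------------------------------------------------------------
# Worked four-vertex example


def consistent_but_unexplained_graph() -> ColoredDigraph:
    """The canonical 4-vertex graph showing that consistency of the
    informative triples does not suffice for best-match-graph-ness.

    Vertices a, ap of one color and b, bp of the other; arcs (a,b), (b,a),
    (bp,a).  Vertex ap has no out-arc, so no tree can explain the graph,
    yet the informative triples {ab|bp, ab|ap, abp|ap} are consistent.
    The constructor re-validates all of these facts on every call.
    """
    G = ColoredDigraph(
        {"a": "red", "ap": "red", "b": "blue", "bp": "blue"},
        [("a", "b"), ("b", "a"), ("bp", "a")],
    )
    assert not G.out_neighbors("ap"), "ap must have no out-arc"
    from .trees import Triple, TripleSet

    expected = TripleSet(
        {Triple.of("a", "b", "bp"), Triple.of("a", "b", "ap"), Triple.of("a", "bp", "ap")},
        G.vertices,
    )
    got = informative_triples(G)
    assert got == expected, f"informative triples changed: {got!r}"
    built = build_tree(got, G.vertices, G.color_map())
    assert built.consistent, "the triple set must be consistent"
    assert bmg_from_tree(built.tree) != G, "the Aho tree must not regenerate the graph"
    return G
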