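"""Vertex-colored digraphs and their thinness structure.

A colored digraph ``(G, sigma)`` has genes as vertices, species as colors,
and an arc ``x -> y`` whenever ``y`` is a candidate best match of ``x``.
Arcs of an actual best match graph always join distinct colors and every
vertex has at least one out-neighbor of every color except its own;
:func:`color_sanity` reports violations of these necessary conditions.

The central structural device is *thinness*: two vertices are equivalent
when they share both their out- and in-neighborhoods.  Neighborhoods are
constant on each class, and the out-neighborhood of a class is itself a
disjoint union of classes, so the whole recognition theory can be phrased
on the class quotient.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Dict, FrozenSet, Iterable, Iterator, List, Mapping, Optional, Set, Tuple

import networkx as nx

__all__ = [
    "GraphError",
    "ColoredDigraph",
    "ColoredGraph",
    "ThinnessPartition",
    "read_graph",
    "write_graph",
    "color_sanity",
    "induced_by_colors",
    "connected_components",
    "thinness_partition",
    "symmetric_part",
]


class GraphError(ValueError):
    """Invalid colored-digraph input."""


class ColoredDigraph:
    """Loop-free digraph with a total vertex coloring.

    Equality is exact: same vertex set, same colors, same arc set (the
    underlying isomorphism notion is color-preserving on an identical
    vertex set, so no isomorphism search is ever needed).
    """

    __slots__ = ("_g",)

    def __init__(self, colors: Mapping[str, str], arcs: Iterable[Tuple[str, str]] = ()):
        g = nx.DiGraph()
        for v, c in colors.items():
            g.add_node(v, color=c)
        for x, y in arcs:
            if x == y:
                raise GraphError(f"loop arc ({x!r},{x!r})")
            for end in (x, y):
                if end not in g:
                    raise GraphError(f"arc endpoint {end!r} is not a declared vertex")
            g.add_edge(x, y)
        self._g = g

    # -- queries -------------------------------------------------------------

    @property
    def vertices(self) -> FrozenSet[str]:
        return frozenset(self._g.nodes)

    @property
    def arcs(self) -> FrozenSet[Tuple[str, str]]:
        return frozenset(self._g.edges)

    def color_of(self, v: str) -> str:
        return self._g.nodes[v]["color"]

    @property
    def colors(self) -> FrozenSet[str]:
        return frozenset(nx.get_node_attributes(self._g, "color").values())

    def color_map(self) -> Dict[str, str]:
        return dict(nx.get_node_attributes(self._g, "color"))

    def color_classes(self) -> Dict[str, FrozenSet[str]]:
        out: Dict[str, Set[str]] = {}
        for v in self._g.nodes:
            out.setdefault(self.color_of(v), set()).add(v)
        return {s: frozenset(vs) for s, vs in out.items()}

    def out_neighbors(self, v: str) -> FrozenSet[str]:
        return frozenset(self._g.successors(v))

    def in_neighbors(self, v: str) -> FrozenSet[str]:
        return frozenset(self._g.predecessors(v))

    def has_arc(self, x: str, y: str) -> bool:
        return self._g.has_edge(x, y)

    def __len__(self) -> int:
        return self._g.number_of_nodes()

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, ColoredDigraph)
            and self.vertices == other.vertices
            and self.color_map() == other.color_map()
            and self.arcs == other.arcs
        )

    def __hash__(self) -> int:
        return hash((self.vertices, frozenset(self.color_map().items()), self.arcs))

    def __repr__(self) -> str:
        return (
            f"ColoredDigraph({len(self)} vertices, {self._g.number_of_edges()} arcs, "
            f"colors={sorted(self.colors)})"
        )

    # -- derived graphs ------------------------------------------------------

    def induced(self, keep: Iterable[str]) -> "ColoredDigraph":
        keep = frozenset(keep)
        stray = keep - self.vertices
        if stray:
            raise GraphError(f"unknown vertices: {sorted(stray)}")
        return ColoredDigraph(
            {v: self.color_of(v) for v in keep},
            ((x, y) for x, y in self._g.edges if x in keep and y in keep),
        )

    def induced_by_colors(self, color_subset: Iterable[str]) -> "ColoredDigraph":
        cs = frozenset(color_subset)
        unknown = cs - self.colors
        if unknown:
            raise GraphError(f"unknown colors: {sorted(unknown)}")
        return self.induced(v for v in self.vertices if self.color_of(v) in cs)

    def weak_components(self) -> Tuple[FrozenSet[str], ...]:
        comps = [frozenset(c) for c in nx.weakly_connected_components(self._g)]
        return tuple(sorted(comps, key=min))

    def is_connected(self) -> bool:
        return len(self) > 0 and nx.is_weakly_connected(self._g)

    def symmetric_part(self) -> "ColoredGraph":
        edges = [(x, y) for x, y in self._g.edges if x < y and self._g.has_edge(y, x)]
        return ColoredGraph(self.color_map(), edges)

    def disjoint_union(self, other: "ColoredDigraph") -> "ColoredDigraph":
        if self.vertices & other.vertices:
            raise GraphError("vertex sets overlap; disjoint union undefined")
        cm = self.color_map()
        cm.update(other.color_map())
        return ColoredDigraph(cm, list(self.arcs) + list(other.arcs))


class ColoredGraph:
    """Undirected vertex-colored graph (the symmetric, reciprocal layer)."""

    __slots__ = ("_g",)

    def __init__(self, colors: Mapping[str, str], edges: Iterable[Tuple[str, str]] = ()):
        g = nx.Graph()
        for v, c in colors.items():
            g.add_node(v, color=c)
        for x, y in edges:
            if x == y:
                raise GraphError(f"loop edge ({x!r},{x!r})")
            if x not in g or y not in g:
                raise GraphError("edge endpoint is not a declared vertex")
            g.add_edge(x, y)
        self._g = g

    @property
    def vertices(self) -> FrozenSet[str]:
        return frozenset(self._g.nodes)

    @property
    def edges(self) -> FrozenSet[FrozenSet[str]]:
        return frozenset(frozenset(e) for e in self._g.edges)

    def color_of(self, v: str) -> str:
        return self._g.nodes[v]["color"]

    @property
    def colors(self) -> FrozenSet[str]:
        return frozenset(nx.get_node_attributes(self._g, "color").values())

    def neighbors(self, v: str) -> FrozenSet[str]:
        return frozenset(self._g.neighbors(v))

    def components(self) -> Tuple[FrozenSet[str], ...]:
        return tuple(sorted((frozenset(c) for c in nx.connected_components(self._g)), key=min))

    def induced_by_colors(self, color_subset: Iterable[str]) -> "ColoredGraph":
        cs = frozenset(color_subset)
        keep = {v for v in self.vertices if self.color_of(v) in cs}
        return ColoredGraph(
            {v: self.color_of(v) for v in keep},
            ((x, y) for x, y in self._g.edges if x in keep and y in keep),
        )


# ---------------------------------------------------------------------------
# Thinness


@dataclass(frozen=True)
class ThinnessPartition:
    """Partition of the vertices into classes of equal (out, in) neighborhoods.

    Classes are addressed by a deterministic id: the lexicographically
    smallest member.  Neighborhoods are stored at class level; by the
    disjoint-union property (N0) the out-neighborhood of a class is an
    exact union of classes, for *any* loop-free digraph.
    """

    members: Dict[str, FrozenSet[str]]  # class id -> vertices
    class_of: Dict[str, str]  # vertex -> class id
    out_nbhd: Dict[str, FrozenSet[str]]  # class id -> class ids
    in_nbhd: Dict[str, FrozenSet[str]]
    color_of: Dict[str, str]  # class id -> color of its members (if uniform)
    per_color_out: Dict[Tuple[str, str], FrozenSet[str]] = field(default_factory=dict)

    @property
    def class_ids(self) -> Tuple[str, ...]:
        return tuple(sorted(self.members))

    @property
    def sinks(self) -> Tuple[str, ...]:
        """Classes with empty in-neighborhood (the set W)."""
        return tuple(a for a in self.class_ids if not self.in_nbhd[a])

    def vertices_of(self, class_ids: Iterable[str]) -> FrozenSet[str]:
        return frozenset(itertools.chain.from_iterable(self.members[a] for a in class_ids))

    def out_vertices(self, class_id: str) -> FrozenSet[str]:
        return self.vertices_of(self.out_nbhd[class_id])

    def in_vertices(self, class_id: str) -> FrozenSet[str]:
        return self.vertices_of(self.in_nbhd[class_id])


def thinness_partition(G: ColoredDigraph) -> ThinnessPartition:
    """Group vertices with identical out- and in-neighborhoods."""
    key_to_members: Dict[Tuple[FrozenSet[str], FrozenSet[str]], Set[str]] = {}
    for v in G.vertices:
        key_to_members.setdefault((G.out_neighbors(v), G.in_neighbors(v)), set()).add(v)

    members = {min(ms): frozenset(ms) for ms in key_to_members.values()}
    class_of = {v: cid for cid, ms in members.items() for v in ms}
    out_nbhd: Dict[str, FrozenSet[str]] = {}
    in_nbhd: Dict[str, FrozenSet[str]] = {}
    color_of: Dict[str, str] = {}
    per_color_out: Dict[Tuple[str, str], FrozenSet[str]] = {}
    for cid in members:
        out_v = G.out_neighbors(cid)
        in_v = G.in_neighbors(cid)
        out_nbhd[cid] = frozenset(class_of[v] for v in out_v)
        in_nbhd[cid] = frozenset(class_of[v] for v in in_v)
        color_of[cid] = G.color_of(cid)
        for s in G.colors:
            per_color_out[(cid, s)] = frozenset(
                class_of[v] for v in out_v if G.color_of(v) == s
            )
    return ThinnessPartition(members, class_of, out_nbhd, in_nbhd, color_of, per_color_out)


# ---------------------------------------------------------------------------
# Spec operations


def read_graph(vertex_table, arc_table) -> ColoredDigraph:
    """Read a digraph from two TSVs: (vertex, color) and (tail, head).

    Comment lines start with '#'; a header whose first field is 'vertex'
    (resp. 'tail') is tolerated.
    """

    def rows(source, header_keys):
        close = isinstance(source, (str, bytes))
        fh = open(source, "rt", encoding="utf-8") if close else source
        try:
            first = True
            for ln, line in enumerate(fh, 1):
                line = line.rstrip("\n")
                if not line.strip() or line.lstrip().startswith("#"):
                    continue
                parts = [p.strip() for p in line.split("\t")]
                if len(parts) != 2:
                    raise GraphError(f"line {ln}: expected 2 tab-separated fields")
                if first and parts[0].lower() in header_keys:
                    first = False
                    continue
                first = False
                yield parts
        finally:
            if close:
                fh.close()

    colors: Dict[str, str] = {}
    for v, c in rows(vertex_table, ("vertex", "id", "leaf")):
        if v in colors:
            raise GraphError(f"duplicate vertex id {v!r}")
        colors[v] = c
    arcs = [(x, y) for x, y in rows(arc_table, ("tail",))]
    return ColoredDigraph(colors, arcs)


def write_graph(G: ColoredDigraph, vertex_handle, arc_handle) -> None:
    """Write the two-TSV representation (sorted, deterministic)."""
    vertex_handle.write("vertex\tcolor\n")
    for v in sorted(G.vertices):
        vertex_handle.write(f"{v}\t{G.color_of(v)}\n")
    arc_handle.write("tail\thead\n")
    for x, y in sorted(G.arcs):
        arc_handle.write(f"{x}\t{y}\n")


def color_sanity(G: ColoredDigraph, require_out: bool = False) -> List[Tuple]:
    """Necessary-condition report for best-match-graph candidates.

    Returns a list of violations: ``("same_color_arc", x, y)`` for arcs
    inside a color class, and — with ``require_out`` — ``("missing_out",
    x, s)`` for a vertex ``x`` with no out-neighbor of color ``s`` (every
    gene must have a best match in every other species).
    """
    violations: List[Tuple] = []
    for x, y in sorted(G.arcs):
        if G.color_of(x) == G.color_of(y):
            violations.append(("same_color_arc", x, y))
    if require_out:
        all_colors = G.colors
        for x in sorted(G.vertices):
            seen = {G.color_of(y) for y in G.out_neighbors(x)}
            for s in sorted(all_colors - seen - {G.color_of(x)}):
                violations.append(("missing_out", x, s))
    return violations


def induced_by_colors(G: ColoredDigraph, color_subset: Iterable[str]) -> ColoredDigraph:
    return G.induced_by_colors(color_subset)


def connected_components(G: ColoredDigraph) -> Tuple[FrozenSet[str], ...]:
    """Weakly connected components (arc directions ignored)."""
    return G.weak_components()


def symmetric_part(G: ColoredDigraph) -> ColoredGraph:
    """The undirected graph of reciprocal (bidirectional) best matches."""
    return G.symmetric_part()
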