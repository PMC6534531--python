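"""Rooted leaf-colored phylogenetic trees.

A gene family is modelled as a rooted phylogenetic tree ``T`` whose leaves
``L`` are genes and whose leaf coloring ``sigma: L -> S`` assigns each gene to
the species it resides in.  "Phylogenetic" means every inner vertex other
than (possibly) the root has at least two children.  The ancestor order
``u <= v`` ("v is an ancestor of u") and the last common ancestor ``lca`` are
the primitives everything else is built on: ``y`` is a best match of ``x``
when no other gene of ``y``'s species has a strictly lower ``lca`` with
``x``.

Leaves are identified by their (string) labels; inner vertices carry opaque
integer ids that are never compared across trees.  Tree equality is defined
up to inner-vertex relabeling via the canonical Newick form: children are
ordered by the smallest leaf label they subtend, and leaf colors are emitted
as ``label|color`` suffixes, so two trees are equal iff their canonical
Newick strings coincide.
"""

from __future__ import annotations

import io
import itertools
import warnings
from dataclasses import dataclass
from typing import Dict, FrozenSet, Iterable, Iterator, Mapping, Optional, Sequence, Set, Tuple

import dendropy

__all__ = [
    "TreeError",
    "NewickParseError",
    "LeafColoredTree",
    "Triple",
    "TripleSet",
    "parse_newick",
    "write_newick",
    "read_color_table",
    "lca",
    "restrict",
    "contract_edges",
    "tree_triples",
    "displays",
]


class TreeError(ValueError):
    """Violation of the rooted-phylogenetic-tree invariants."""


class NewickParseError(TreeError):
    """Malformed Newick input; the message carries the source position."""


# ---------------------------------------------------------------------------
# Rooted triples


@dataclass(frozen=True, order=True)
class Triple:
    """A rooted triple ``xy|z``: the path x--y avoids the path z--root.

    The in-pair is stored sorted so that ``xy|z`` and ``yx|z`` compare equal.
    """

    pair: Tuple[str, str]
    outgroup: str

    @classmethod
    def of(cls, x: str, y: str, z: str) -> "Triple":
        if len({x, y, z}) != 3:
            raise ValueError(f"triple needs three distinct leaves, got {x, y, z}")
        return cls(pair=(x, y) if x <= y else (y, x), outgroup=z)

    def leaves(self) -> FrozenSet[str]:
        return frozenset((*self.pair, self.outgroup))

    def __str__(self) -> str:  # "x,y|z"
        return f"{self.pair[0]},{self.pair[1]}|{self.outgroup}"

    @classmethod
    def from_string(cls, text: str) -> "Triple":
        inpair, _, out = text.strip().partition("|")
        x, _, y = inpair.partition(",")
        if not (x and y and out):
            raise ValueError(f"cannot parse triple {text!r}; expected 'x,y|z'")
        return cls.of(x.strip(), y.strip(), out.strip())


class TripleSet:
    """A set of rooted triples over a fixed leaf universe."""

    __slots__ = ("triples", "leaf_universe")

    def __init__(self, triples: Iterable[Triple] = (), leaf_universe: Iterable[str] = ()):
        self.triples: FrozenSet[Triple] = frozenset(triples)
        self.leaf_universe: FrozenSet[str] = frozenset(leaf_universe)
        stray = frozenset().union(*(t.leaves() for t in self.triples)) - self.leaf_universe if self.triples else frozenset()
        if stray:
            raise ValueError(f"triple leaves outside universe: {sorted(stray)}")

    def __iter__(self) -> Iterator[Triple]:
        return iter(self.triples)

    def __len__(self) -> int:
        return len(self.triples)

    def __contains__(self, t: Triple) -> bool:
        return t in self.triples

    def __eq__(self, other: object) -> bool:
        return (
            isinstance(other, TripleSet)
            and self.triples == other.triples
            and self.leaf_universe == other.leaf_universe
        )

    def __hash__(self) -> int:
        return hash((self.triples, self.leaf_universe))

    def __le__(self, other: "TripleSet") -> bool:
        return self.triples <= other.triples

    def __or__(self, other: "TripleSet") -> "TripleSet":
        return TripleSet(self.triples | other.triples, self.leaf_universe | other.leaf_universe)

    def restrict_to(self, leaves: Iterable[str]) -> "TripleSet":
        keep = frozenset(leaves)
        return TripleSet((t for t in self.triples if t.leaves() <= keep), keep & self.leaf_universe)

    def __repr__(self) -> str:
        return f"TripleSet({{{', '.join(sorted(map(str, self.triples)))}}})"


# ---------------------------------------------------------------------------
# The tree proper


class LeafColoredTree:
    """A rooted phylogenetic tree with a total leaf coloring.

    Parameters
    ----------
    children:
        Mapping vertex -> sequence of child vertices.  Leaves map to an
        empty sequence (or may be absent).  Leaf vertices must be strings;
        inner-vertex ids are arbitrary hashables (ints by convention).
    root:
        The root vertex.
    color_of:
        Mapping leaf label -> color; must be total on the leaves.
    """

    __slots__ = (
        "root",
        "children",
        "parent",
        "color_of",
        "depth",
        "_subtree_leaves",
        "_newick_cache",
    )

    def __init__(
        self,
        children: Mapping[object, Sequence[object]],
        root: object,
        color_of: Mapping[str, str],
    ):
        kids: Dict[object, Tuple[object, ...]] = {
            v: tuple(children.get(v, ())) for v in self._all_vertices(children, root)
        }
        parent: Dict[object, object] = {}
        for v, cs in kids.items():
            for c in cs:
                if c in parent:
                    raise TreeError(f"vertex {c!r} has more than one parent")
                parent[c] = v
        if root in parent:
            raise TreeError("root must not have a parent")
        # reachability from the root (connected + acyclic given unique parents)
        seen: Set[object] = set()
        stack = [root]
        while stack:
            v = stack.pop()
            if v in seen:
                raise TreeError("cycle detected")
            seen.add(v)
            stack.extend(kids[v])
        if seen != set(kids):
            raise TreeError("tree is not connected")

        leaves = {v for v, cs in kids.items() if not cs}
        for lf in leaves:
            if not isinstance(lf, str):
                raise TreeError(f"leaf {lf!r} must be a string label")
            if lf not in color_of:
                raise TreeError(f"leaf {lf!r} has no color")
        for v, cs in kids.items():
            if cs and len(cs) < 2 and v != root:
                raise TreeError(f"inner vertex {v!r} has a single child (not phylogenetic)")
        if kids[root] and len(kids[root]) < 2:
            raise TreeError("root with a single child; suppress it before construction")

        self.root = root
        self.color_of: Dict[str, str] = {lf: color_of[lf] for lf in leaves}
        self.parent = parent
        # depths and per-vertex leaf sets
        self.depth: Dict[object, int] = {root: 0}
        order = [root]
        tmp_kids = kids
        for v in order:
            for c in tmp_kids[v]:
                self.depth[c] = self.depth[v] + 1
                order.append(c)
        sub: Dict[object, FrozenSet[str]] = {}
        for v in reversed(order):
            if not tmp_kids[v]:
                sub[v] = frozenset((v,))
            else:
                sub[v] = frozenset().union(*(sub[c] for c in tmp_kids[v]))
        self._subtree_leaves = sub
        # canonical child order: by smallest subtended leaf label
        self.children = {v: tuple(sorted(cs, key=lambda c: min(sub[c]))) for v, cs in kids.items()}
        self._newick_cache: Dict[bool, str] = {}

    @staticmethod
    def _all_vertices(children: Mapping[object, Sequence[object]], root: object) -> Set[object]:
        vs = {root}
        vs.update(children)
        for cs in children.values():
            vs.update(cs)
        return vs

    # -- basic queries ------------------------------------------------------

    @property
    def vertices(self) -> FrozenSet[object]:
        return frozenset(self.children)

    @property
    def leaves(self) -> FrozenSet[str]:
        return self._subtree_leaves[self.root]

    @property
    def color_set(self) -> FrozenSet[str]:
        return frozenset(self.color_of.values())

    def color_classes(self) -> Dict[str, FrozenSet[str]]:
        out: Dict[str, Set[str]] = {}
        for lf, s in self.color_of.items():
            out.setdefault(s, set()).add(lf)
        return {s: frozenset(v) for s, v in out.items()}

    def is_leaf(self, v: object) -> bool:
        return not self.children[v]

    def subtree_leaves(self, v: object) -> FrozenSet[str]:
        return self._subtree_leaves[v]

    def edges(self) -> Iterator[Tuple[object, object]]:
        for v, cs in self.children.items():
            for c in cs:
                yield (v, c)

    def inner_edges(self) -> Tuple[Tuple[object, object], ...]:
        return tuple((u, v) for u, v in self.edges() if not self.is_leaf(v))

    def ancestors(self, v: object) -> Iterator[object]:
        """``v`` and all its ancestors, bottom-up to the root."""
        while True:
            yield v
            if v == self.root:
                return
            v = self.parent[v]

    def lca(self, vertices: Iterable[object]) -> object:
        vs = list(vertices)
        if not vs:
            raise ValueError("lca of an empty set is undefined")
        a = vs[0]
        for b in vs[1:]:
            a = self._lca2(a, b)
        return a

    def _lca2(self, a: object, b: object) -> object:
        da, db = self.depth[a], self.depth[b]
        while da > db:
            a = self.parent[a]
            da -= 1
        while db > da:
            b = self.parent[b]
            db -= 1
        while a != b:
            a = self.parent[a]
            b = self.parent[b]
        return a

    # -- construction helpers ----------------------------------------------

    @classmethod
    def from_nested(cls, nested: object, color_of: Mapping[str, str]) -> "LeafColoredTree":
        """Build from nested tuples of leaf labels, e.g. ``(("a","b"),"c")``."""
        children: Dict[object, list] = {}
        counter = itertools.count()

        def walk(node: object) -> object:
            if isinstance(node, str):
                children[node] = []
                return node
            vid = next(counter)
            children[vid] = [walk(c) for c in node]
            return vid

        root = walk(nested)
        return cls(children, root, color_of)

    def to_nested(self) -> object:
        def walk(v: object) -> object:
            if self.is_leaf(v):
                return v
            return tuple(walk(c) for c in self.children[v])

        return walk(self.root)

    def _rebuild(self, children: Mapping[object, Sequence[object]], root: object) -> "LeafColoredTree":
        leaves = {v for v in self._all_vertices(children, root) if not children.get(v, ())}
        return LeafColoredTree(children, root, {lf: self.color_of[lf] for lf in leaves})

    # -- Newick -------------------------------------------------------------

    def newick(self, with_colors: bool = True) -> str:
        if with_colors not in self._newick_cache:

            def walk(v: object) -> str:
                if self.is_leaf(v):
                    return f"{v}|{self.color_of[v]}" if with_colors else str(v)
                return "(" + ",".join(walk(c) for c in self.children[v]) + ")"

            self._newick_cache[with_colors] = walk(self.root) + ";"
        return self._newick_cache[with_colors]

    def __eq__(self, other: object) -> bool:
        return isinstance(other, LeafColoredTree) and self.newick() == other.newick()

    def __hash__(self) -> int:
        return hash(self.newick())

    def __repr__(self) -> str:
        return f"LeafColoredTree({self.newick()})"

    # -- spec operations (also exposed as module functions) ------------------

    def restrict(self, keep_leaves: Iterable[str]) -> "LeafColoredTree":
        keep = frozenset(keep_leaves)
        if not keep:
            raise ValueError("cannot restrict to an empty leaf set")
        if not keep <= self.leaves:
            raise ValueError(f"leaves not in tree: {sorted(keep - self.leaves)}")
        if len(keep) == 1:
            (lf,) = keep
            return LeafColoredTree({lf: ()}, lf, {lf: self.color_of[lf]})
        new_root = self.lca(keep)

        def prune(v: object) -> Optional[object]:
            # returns the surviving representative of v's subtree, with
            # degree-2 vertices suppressed on the way up
            if self.is_leaf(v):
                return v if v in keep else None
            survivors = [w for w in (prune(c) for c in self.children[v]) if w is not None]
            if not survivors:
                return None
            if len(survivors) == 1:
                return survivors[0]
            new_children[v] = survivors
            return v

        new_children: Dict[object, list] = {}
        top = prune(new_root)
        if self.is_leaf(top) if top is not None else False:
            return LeafColoredTree({top: ()}, top, {top: self.color_of[top]})
        for v in list(new_children):
            for c in new_children[v]:
                new_children.setdefault(c, [])
        return self._rebuild(new_children, top)

    def contract_edges(self, edges: Iterable[Tuple[object, object]]) -> "LeafColoredTree":
        to_contract = set(edges)
        inner = set(self.inner_edges())
        bad = to_contract - inner
        if bad:
            raise ValueError(f"not inner edges of this tree: {sorted(map(str, bad))}")
        if not to_contract:
            return self
        merged: Dict[object, object] = {}

        def find(v: object) -> object:
            while v in merged:
                v = merged[v]
            return v

        children = {v: list(cs) for v, cs in self.children.items()}
        for u, v in to_contract:
            u = find(u)
            # v is never a contraction target twice (each edge has a unique child)
            children[u] = [c for c in children[u] if c != v] + children.pop(v)
            merged[v] = u
        return self._rebuild(children, find(self.root))

    def triples(self) -> TripleSet:
        out: Set[Triple] = set()
        leaves = sorted(self.leaves)
        pair_lca = {
            (x, y): self._lca2(x, y) for x, y in itertools.combinations(leaves, 2)
        }
        for x, y, z in itertools.combinations(leaves, 3):
            lxy, lxz, lyz = pair_lca[(x, y)], pair_lca[(x, z)], pair_lca[(y, z)]
            dxy, dxz, dyz = self.depth[lxy], self.depth[lxz], self.depth[lyz]
            top = min(dxy, dxz, dyz)
            if dxy > top and dxz == dyz == top:
                out.add(Triple.of(x, y, z))
            elif dxz > top and dxy == dyz == top:
                out.add(Triple.of(x, z, y))
            elif dyz > top and dxy == dxz == top:
                out.add(Triple.of(y, z, x))
        return TripleSet(out, self.leaves)

    def displays(self, small: "LeafColoredTree") -> bool:
        """True iff ``small`` arises from a subtree of ``self`` by contractions.

        Decided via rooted-triple containment after restriction, which is
        equivalent for rooted trees on the given leaf sets.
        """
        if not small.leaves <= self.leaves:
            return False
        for lf in small.leaves:
            if small.color_of[lf] != self.color_of[lf]:
                raise ValueError(f"color mismatch on shared leaf {lf!r}")
        restricted = self.restrict(small.leaves)
        return small.triples().triples <= restricted.triples().triples


# ---------------------------------------------------------------------------
# I/O


def read_color_table(source) -> Dict[str, str]:
    """Read a 2-column TSV ``leaf<TAB>color``; '#' starts a comment line.

    ``source`` is a path or an open text handle.  A header line is tolerated
    if its first field is exactly 'leaf' or 'vertex'.
    """
    close = False
    if isinstance(source, (str, bytes)):
        fh = open(source, "rt", encoding="utf-8")
        close = True
    else:
        fh = source
    try:
        table: Dict[str, str] = {}
        for ln, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line.strip() or line.lstrip().startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"line {ln}: expected 2 tab-separated fields, got {len(parts)}")
            key, val = (p.strip() for p in parts)
            if ln == 1 and key.lower() in ("leaf", "vertex"):
                continue
            if key in table:
                raise ValueError(f"line {ln}: duplicate leaf {key!r}")
            table[key] = val
        return table
    finally:
        if close:
            fh.close()


def parse_newick(text: str, colors: Optional[Mapping[str, str]] = None) -> LeafColoredTree:
    """Parse a Newick string into a :class:`LeafColoredTree`.

    Colors come either from the ``colors`` table (keyed by the full leaf
    label) or, if no table is given, from inline ``label|color`` suffixes.
    A root with a single child is suppressed with a warning; unary inner
    vertices are likewise suppressed so the result is phylogenetic.
    """
    try:
        dtree = dendropy.Tree.get(
            data=text,
            schema="newick",
            suppress_internal_node_taxa=True,
        )
    except Exception as exc:  # dendropy reports line/column in the message
        raise NewickParseError(f"malformed Newick: {exc}") from exc

    counter = itertools.count()
    children: Dict[object, list] = {}
    color_of: Dict[str, str] = {}

    def leaf_label(node) -> str:
        raw = node.taxon.label if node.taxon is not None else node.label
        if raw is None:
            raise NewickParseError("leaf without a label")
        if colors is not None:
            if raw not in colors:
                raise NewickParseError(f"leaf {raw!r} missing from the color table")
            color_of[raw] = colors[raw]
            return raw
        name, sep, col = raw.rpartition("|")
        if not sep or not name or not col:
            raise NewickParseError(
                f"leaf {raw!r} carries no color: supply a color table or use 'label|color'"
            )
        color_of[name] = col
        return name

    def walk(node) -> object:
        if node.is_leaf():
            lab = leaf_label(node)
            if lab in children:
                raise NewickParseError(f"duplicate leaf label {lab!r}")
            children[lab] = []
            return lab
        kids = [walk(c) for c in node.child_nodes()]
        if len(kids) == 1:
            warnings.warn("suppressing a unary vertex in Newick input", stacklevel=3)
            return kids[0]
        vid = next(counter)
        children[vid] = kids
        return vid

    root = walk(dtree.seed_node)
    if not children[root] and len(children) == 1:
        warnings.warn("degenerate single-leaf tree", stacklevel=2)
    return LeafColoredTree(children, root, color_of)


def write_newick(tree: LeafColoredTree, with_colors: bool = True) -> str:
    """Canonical Newick: children sorted by smallest leaf; 'label|color' leaves."""
    return tree.newick(with_colors=with_colors)


# -- module-level function forms of the operations --------------------------


def lca(tree: LeafColoredTree, vertices: Iterable[object]) -> object:
    return tree.lca(vertices)


def restrict(tree: LeafColoredTree, keep_leaves: Iterable[str]) -> LeafColoredTree:
    return tree.restrict(keep_leaves)


def contract_edges(tree: LeafColoredTree, edges: Iterable[Tuple[object, object]]) -> LeafColoredTree:
    return tree.contract_edges(edges)


def tree_triples(tree: LeafColoredTree) -> TripleSet:
    return tree.triples()


def displays(big: LeafColoredTree, small: LeafColoredTree) -> bool:
    return big.displays(small)
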