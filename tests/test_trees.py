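"""Tree representation, Newick I/O, lca, restriction, contraction, triples."""

import itertools
import random

import pytest
from hypothesis import given, settings, strategies as st

from bmgraph.fixtures import RandomTreeSpec, enumerate_topologies, random_colored_tree
from bmgraph.trees import (
    LeafColoredTree,
    NewickParseError,
    Triple,
    TreeError,
    parse_newick,
    write_newick,
)
from conftest import iter_random_trees

ABC = {"a": "red", "b": "blue", "c": "blue"}


class TestParseWrite:
    def test_basic_parse(self):
        t = parse_newick("((a,b),c);", ABC)
        assert t.leaves == {"a", "b", "c"}
        assert t.color_of == ABC
        # one inner vertex besides the root
        assert len(t.vertices) - len(t.leaves) == 2

    def test_cherry_roundtrip_string(self):
        t = parse_newick("(a,b);", {"a": "red", "b": "blue"})
        assert write_newick(t) == "(a|red,b|blue);"

    def test_inline_colors(self):
        t = parse_newick("((a|red,b|blue),c|blue);")
        assert t.color_of == ABC

    def test_nested_singleton_collapses_with_warning(self):
        with pytest.warns(UserWarning):
            t = parse_newick("((a));", {"a": "red"})
        assert t.leaves == {"a"}
        assert t.root == "a"

    @pytest.mark.parametrize(
        "text,colors",
        [
            ("((a,b),c;", ABC),  # unbalanced parentheses
            ("((a,a),c);", {"a": "red", "c": "blue"}),  # duplicate leaf
            ("((a,b),c);", {"a": "red", "b": "blue"}),  # leaf without color
            ("(a,b);", None),  # inline colors required but absent
        ],
    )
    def test_errors(self, text, colors):
        with pytest.raises(NewickParseError):
            parse_newick(text, colors)

    def test_canonicalization_is_child_order_invariant(self):
        t1 = LeafColoredTree.from_nested((("b", "a"), "c"), ABC)
        t2 = LeafColoredTree.from_nested(("c", ("a", "b")), ABC)
        assert write_newick(t1) == write_newick(t2)
        assert t1 == t2

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_parse_write_roundtrip(self, seed):
        rng = random.Random(seed)
        n = rng.randint(2, 25)
        t = random_colored_tree(RandomTreeSpec(n, rng.randint(1, min(4, n)), seed=seed))
        assert parse_newick(write_newick(t)) == t

    def test_non_phylogenetic_rejected(self):
        with pytest.raises(TreeError):
            LeafColoredTree({0: [1], 1: ["a", "b"], "a": [], "b": []}, 0, {"a": "r", "b": "r"})


class TestLca:
    def test_reflexive(self):
        t = parse_newick("((a,b),c);", ABC)
        assert t.lca(["a"]) == "a"

    def test_examples(self):
        t = parse_newick("((a,b),c);", ABC)
        assert t.lca(["a", "b"]) != t.root
        assert t.lca(["a", "c"]) == t.root
        assert t.lca(["a", "b", "c"]) == t.root

    @settings(max_examples=100, derandomize=True)
    @given(st.integers(0, 10**6))
    def test_associativity_identity(self, seed):
        """lca(A ∪ B) = lca(lca(A), lca(B)) on random trees."""
        rng = random.Random(seed)
        t = random_colored_tree(RandomTreeSpec(rng.randint(3, 20), 2, seed=seed))
        leaves = sorted(t.leaves)
        a, b, c = rng.sample(leaves, 3)
        assert t.lca([t.lca([a, b]), c]) == t.lca([a, b, c])

    def test_empty_set_rejected(self):
        t = parse_newick("(a,b);", {"a": "r", "b": "b"})
        with pytest.raises(ValueError):
            t.lca([])


class TestRestrict:
    def test_identity(self):
        t = parse_newick("((a,b),c);", ABC)
        assert t.restrict(t.leaves) == t

    def test_cherry(self):
        t = parse_newick("((a,b),c);", ABC)
        r = t.restrict({"a", "c"})
        assert write_newick(r) == "(a|red,c|blue);"

    def test_unknown_leaf_rejected(self):
        t = parse_newick("((a,b),c);", ABC)
        with pytest.raises(ValueError):
            t.restrict({"a", "z"})
        with pytest.raises(ValueError):
            t.restrict(set())

    def test_restriction_filters_triples(self):
        """r(T|L') = { xy|z in r(T) : x,y,z in L' } on random trees."""
        rng = random.Random(7)
        for t in iter_random_trees(30, max_leaves=12, seed0=7):
            sub = frozenset(rng.sample(sorted(t.leaves), rng.randint(1, len(t.leaves))))
            expected = {tr for tr in t.triples() if tr.leaves() <= sub}
            assert t.restrict(sub).triples().triples == expected


class TestContract:
    def test_empty_is_identity(self):
        t = parse_newick("((a,b),c);", ABC)
        assert t.contract_edges([]) == t

    def test_full_contraction_gives_star(self):
        colors = {"a1": "r", "a2": "r", "b1": "b", "b2": "b"}
        t = LeafColoredTree.from_nested((("a1", "a2"), ("b1", "b2")), colors)
        star = t.contract_edges(t.inner_edges())
        assert star.children[star.root] == ("a1", "a2", "b1", "b2")

    def test_outer_edge_rejected(self):
        t = parse_newick("((a,b),c);", ABC)
        outer = next(e for e in t.edges() if t.is_leaf(e[1]))
        with pytest.raises(ValueError):
            t.contract_edges([outer])

    def test_commutativity(self):
        """contract(A ∪ B) = contract(contract(A), B) on random trees."""
        rng = random.Random(11)
        for t in iter_random_trees(30, max_leaves=15, seed0=11):
            inner = list(t.inner_edges())
            if len(inner) < 2:
                continue
            picked = rng.sample(inner, rng.randint(2, len(inner)))
            a, b = picked[: len(picked) // 2], picked[len(picked) // 2 :]
            once = t.contract_edges(picked)
            t_a = t.contract_edges(a)
            # re-address the b-edges by their child endpoint, which survives
            twice = t_a.contract_edges([(t_a.parent[v], v) for (_u, v) in b])
            assert once == twice


class TestTriples:
    def test_star_has_none(self):
        t = LeafColoredTree.from_nested(("a", "b", "c", "d"), dict.fromkeys("abcd", "r"))
        assert len(t.triples()) == 0

    def test_resolved_triple(self):
        t = parse_newick("((a,b),c);", ABC)
        assert t.triples().triples == {Triple.of("a", "b", "c")}

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_caterpillar_resolves_every_subset(self, n):
        labels = [f"x{i}" for i in range(n)]
        nested = labels[0]
        for lab in labels[1:]:
            nested = (nested, lab)
        t = LeafColoredTree.from_nested(nested, dict.fromkeys(labels, "r"))
        n_choose_3 = n * (n - 1) * (n - 2) // 6
        assert len(t.triples()) == n_choose_3


def _brute_force_displays(big, small):
    """Contraction-search oracle: restrict, then try every inner-edge subset."""
    if not small.leaves <= big.leaves:
        return False
    r = big.restrict(small.leaves)
    inner = list(r.inner_edges())
    for k in range(len(inner) + 1):
        for sub in itertools.combinations(inner, k):
            if r.contract_edges(sub) == small:
                return True
    return False


class TestDisplays:
    def test_reflexive_and_star(self):
        colors = dict.fromkeys(("a", "b", "c", "d"), "r")
        binary = LeafColoredTree.from_nested((("a", "b"), ("c", "d")), colors)
        star = LeafColoredTree.from_nested(("a", "b", "c", "d"), colors)
        assert binary.displays(binary)
        assert binary.displays(star)
        assert not star.displays(binary)

    def test_color_mismatch_rejected(self):
        t1 = parse_newick("(a,b);", {"a": "red", "b": "blue"})
        t2 = parse_newick("(a,b);", {"a": "blue", "b": "red"})
        with pytest.raises(ValueError):
            t1.displays(t2)

    def test_agrees_with_contraction_search(self):
        """Triple-containment test vs exhaustive contraction on small trees."""
        colors4 = dict.fromkeys([f"l{i}" for i in range(4)], "r")
        trees4 = [
            LeafColoredTree.from_nested(topo, colors4)
            for topo in enumerate_topologies(colors4)
        ]
        for big, small in itertools.product(trees4, trees4):
            assert big.displays(small) == _brute_force_displays(big, small)

        rng = random.Random(3)
        colors5 = dict.fromkeys([f"l{i}" for i in range(5)], "r")
        trees5 = [
            LeafColoredTree.from_nested(topo, colors5)
            for topo in enumerate_topologies(colors5)
        ]
        for _ in range(300):
            big, small = rng.choice(trees5), rng.choice(trees5)
            assert big.displays(small) == _brute_force_displays(big, small)
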