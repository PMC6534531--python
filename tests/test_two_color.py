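"""Neighborhood axioms, reachable sets, hierarchy, two-color recognition."""

import itertools

import pytest

from bmgraph.bmg import bmg_from_tree, class_roots, lrt_by_contraction
from bmgraph.digraphs import ColoredDigraph, thinness_partition
from bmgraph.fixtures import (
    consistent_but_unexplained_graph,
    minimal_counterexample_search,
)
from bmgraph.trees import LeafColoredTree, parse_newick
from bmgraph.two_color import (
    check_axioms,
    extended_reachable_set,
    hierarchy_of_extended_sets,
    lrt_from_hierarchy,
    q_set,
    reachable_set,
    recognize_2cbmg,
    sink_classes,
)
from conftest import iter_random_trees

K11 = ColoredDigraph({"a": "red", "b": "blue"}, [("a", "b"), ("b", "a")])

# Two sink classes at different depths; the shallower one reaches everything
# that is not a sink (built to exercise the multiple-sink branch).
TWO_SINKS_TREE = LeafColoredTree.from_nested(
    ("b1", (("b2", ("a1", "b3")), ("a2", "b4"))),
    {"a1": "red", "a2": "red", "b1": "blue", "b2": "blue", "b3": "blue", "b4": "blue"},
)


def two_color_bmgs(count, seed0):
    for t in iter_random_trees(count, max_leaves=16, colors=(2, 2), seed0=seed0):
        yield t, bmg_from_tree(t)


class TestAxioms:
    def test_hold_on_true_bmgs(self):
        for t, G in two_color_bmgs(60, seed0=201):
            for comp in G.weak_components():
                assert check_axioms(G.induced(comp)).all_hold

    def test_trivial_on_single_class_pair(self):
        assert check_axioms(K11).all_hold

    def test_minimal_counterexample_is_rejected_somewhere(self):
        bad = minimal_counterexample_search().example
        assert not recognize_2cbmg(bad).is_bmg

    def test_wrong_color_count_rejected(self):
        with pytest.raises(ValueError):
            check_axioms(ColoredDigraph({"a": "r"}))


class TestSinkClasses:
    def test_single_sink_reaches_the_rest(self):
        G = bmg_from_tree(parse_newick("((a,b),c);", {"a": "red", "b": "blue", "c": "blue"}))
        rep = sink_classes(G)
        assert rep.case == "single" and rep.sinks == ("c",)
        assert reachable_set(G, thinness_partition(G), "c") == {"a", "b"}

    def test_bidirectional_pair_has_no_sinks(self):
        rep = sink_classes(K11)
        assert rep.case == "empty" and rep.consistent

    def test_two_sinks_with_unique_maximal(self):
        G = bmg_from_tree(TWO_SINKS_TREE)
        P = thinness_partition(G)
        rep = sink_classes(G, P)
        assert rep.case == "multiple" and len(rep.sinks) == 2
        assert rep.consistent and rep.alpha_star == "b1"
        assert reachable_set(G, P, "b1") == G.vertices - P.vertices_of(rep.sinks)

    def test_trichotomy_on_random_bmgs(self):
        for t, G in two_color_bmgs(60, seed0=211):
            for comp in G.weak_components():
                assert sink_classes(G.induced(comp)).consistent


class TestReachableSets:
    def test_three_leaf_example(self):
        G = bmg_from_tree(parse_newick("((a,b),c);", {"a": "red", "b": "blue", "c": "blue"}))
        P = thinness_partition(G)
        assert reachable_set(G, P, "c") == {"a", "b"}
        assert reachable_set(G, P, "a") == {"a", "b"}

    def test_out_degree_zero_class_reaches_nothing(self):
        G = ColoredDigraph({"a": "red", "b": "blue"}, [("a", "b")])
        P = thinness_partition(G)
        assert reachable_set(G, P, "b") == frozenset()

    def test_traversal_equals_two_step_closure(self):
        """R(alpha) = N(alpha) ∪ N(N(alpha)) once the axioms hold."""
        for t, G in two_color_bmgs(60, seed0=221):
            for comp in G.weak_components():
                sub = G.induced(comp)
                P = thinness_partition(sub)
                for a in P.class_ids:
                    one = P.out_vertices(a)
                    two = P.vertices_of(
                        frozenset(
                            itertools.chain.from_iterable(
                                P.out_nbhd[b] for b in P.out_nbhd[a]
                            )
                        )
                    )
                    assert reachable_set(sub, P, a) == one | two


class TestQSet:
    def test_distinct_in_neighborhoods_give_trivial_q(self):
        G = bmg_from_tree(parse_newick("((a,b),c);", {"a": "red", "b": "blue", "c": "blue"}))
        P = thinness_partition(G)
        for a in P.class_ids:
            assert q_set(P, a) == P.members[a]

    def test_equal_in_nested_out_gives_proper_superset(self):
        G = bmg_from_tree(TWO_SINKS_TREE)
        P = thinness_partition(G)
        # both sinks share the (empty) in-neighborhood; outs are nested
        assert q_set(P, "b1") == {"b1", "b2"}
        assert q_set(P, "b2") == {"b2"}

    def test_monotone_transitivity(self):
        """beta ⊆ Q(alpha) implies Q(beta) ⊆ Q(alpha)."""
        for t, G in two_color_bmgs(50, seed0=231):
            P = thinness_partition(G)
            for a in P.class_ids:
                qa = q_set(P, a)
                for b in P.class_ids:
                    if P.members[b] <= qa:
                        assert q_set(P, b) <= qa


class TestHierarchy:
    def test_single_pair(self):
        res = hierarchy_of_extended_sets(K11)
        assert res.ok
        assert res.hierarchy.sets == {frozenset({"a", "b"})}

    def test_bmgs_yield_hierarchy_with_full_universe(self):
        for t, G in two_color_bmgs(50, seed0=241):
            for comp in G.weak_components():
                sub = G.induced(comp)
                res = hierarchy_of_extended_sets(sub)
                assert res.ok
                assert sub.vertices in res.hierarchy.sets

    def test_three_leaf_worked_example(self):
        """R' sets of the 3-leaf graph are {a,b} and {a,b,c}; the Hasse tree
        with attached class members rebuilds the original topology."""
        G = bmg_from_tree(parse_newick("((a,b),c);", {"a": "red", "b": "blue", "c": "blue"}))
        P = thinness_partition(G)
        sets = {extended_reachable_set(G, P, a) for a in P.class_ids}
        assert sets == {frozenset({"a", "b"}), frozenset({"a", "b", "c"})}
        res = hierarchy_of_extended_sets(G, P)
        lrt = lrt_from_hierarchy(G, P, res.hierarchy)
        assert lrt.newick() == "((a|red,b|blue),c|blue);"

    def test_cherry_from_single_pair(self):
        P = thinness_partition(K11)
        res = hierarchy_of_extended_sets(K11, P)
        lrt = lrt_from_hierarchy(K11, P, res.hierarchy)
        assert lrt.newick() == "(a|red,b|blue);"


class TestRecognition:
    def test_round_trip_on_random_trees(self):
        for t, G in two_color_bmgs(60, seed0=251):
            res = recognize_2cbmg(G)
            assert res.is_bmg
            assert bmg_from_tree(res.lrt) == G
            assert res.lrt == lrt_by_contraction(t, G)

    def test_worked_example_rejected_for_missing_out_arc(self):
        res = recognize_2cbmg(consistent_but_unexplained_graph())
        assert not res.is_bmg
        assert res.certificate["stage"] == "sanity"

    def test_minimal_counterexample_rejected(self):
        assert not recognize_2cbmg(minimal_counterexample_search().example).is_bmg

    def test_root_configuration_case_analysis(self):
        """For class pairs of distinct colors exactly one of the four
        membership patterns holds, and it matches the relative position of
        the class roots in an explaining tree."""
        for t, G in two_color_bmgs(40, seed0=261):
            if not G.is_connected():
                continue
            P = thinness_partition(G)
            roots = class_roots(t, G, P)
            for a, b in itertools.combinations(P.class_ids, 2):
                if P.color_of[a] == P.color_of[b]:
                    continue
                ra, rb = roots.root_of(a), roots.root_of(b)
                a_in = a in P.out_nbhd[b]
                b_in = b in P.out_nbhd[a]
                if a_in and b_in:
                    assert ra == rb
                elif a_in:
                    assert t.lca((ra, rb)) == rb and ra != rb
                elif b_in:
                    assert t.lca((ra, rb)) == ra and ra != rb
                else:
                    assert t.lca((ra, rb)) not in (ra, rb)
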