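"""Union/intersection closures, graph-derived local levels, closed-test oracle."""

import numpy as np
import pytest

import shortfocus as sf
from shortfocus.closure import antichain_node_count, minimal_generating_subset

from conftest import random_nested_dag, random_pvalues
from test_graphtest import figure4_graph, holm_graph

ALPHA = 0.05


def nested_pair_family():
    """Two partially nested parameter hypotheses per side, token-encoded.

    The token sets realize the implications: a stricter one-sided null
    (θ ≤ −δ) implies the looser one (θ ≤ 0), so its evidence set is a
    strict superset."""
    return sf.HypothesisFamily.from_sets(
        {"H1": {"a1", "a2"}, "H2": {"a1"}, "H3": {"b1", "b2"}, "H4": {"b1"}}
    )


class TestClosureCounts:
    def test_toy_generic_position_14(self):
        assert sf.close_under_unions(sf.toy_memberships()).k_closure == 14

    def test_nested14_counts(self):
        # the 14 nested sets: 383 truly distinct unions; 574 closed-graph
        # nodes when nodes are identified by generating antichains (the
        # convention of closed-graph constructions that never merge
        # content-equal unions of incomparable sets)
        member = sf.nested14_memberships()
        assert sf.close_under_unions(member).k_closure == 383
        assert antichain_node_count(member) == 574

    def test_nested_example_closure_is_8(self):
        graph = sf.close_family(nested_pair_family())
        assert graph.k_closure == 8
        unions = {n.union for n in graph.nodes}
        assert frozenset({"a1", "a2", "b1", "b2"}) in unions  # H13

    def test_unrestricted_four_is_15(self):
        fam = sf.HypothesisFamily.from_sets({f"H{i}": {f"t{i}"} for i in range(1, 5)})
        assert sf.close_family(fam).k_closure == 15

    def test_single_set_and_nested_pair(self):
        assert sf.close_under_unions({"A": {"x"}}).k_closure == 1
        fam = sf.HypothesisFamily.from_sets({"H1": {"x", "y"}, "H2": {"x"}})
        assert sf.close_family(fam).k_closure == 2

    def test_count_invariant_to_input_order(self):
        member = sf.nested14_memberships()
        shuffled = dict(reversed(list(member.items())))
        assert (sf.close_under_unions(member).k_closure
                == sf.close_under_unions(shuffled).k_closure)

    def test_unrestricted_equality_iff(self):
        rng = np.random.default_rng(3)
        for _ in range(10):
            dag = random_nested_dag(rng, max_terms=5)
            graph = sf.close_under_unions(dag.membership)
            unrestricted = not any(
                dag.membership[a] < dag.membership[b]
                for a in dag.terms for b in dag.terms if a != b
            )
            assert (graph.k_closure == 2 ** dag.m - 1) == unrestricted


class TestFocusClosure:
    def test_root_focus_equals_full_closure(self, toy):
        fl = sf.validate_focus_level(toy, {"A"})
        full = sf.close_under_unions(toy.membership)
        focused = sf.focus_closure(toy, fl)
        assert {n.union for n in focused.nodes} == {n.union for n in full.nodes}
        assert focused.k_closure == 14

    def test_leaf_focus_adds_no_nodes(self, toy):
        fl = sf.validate_focus_level(toy, {"C", "D", "E"})
        focused = sf.focus_closure(toy, fl)
        assert {n.union for n in focused.nodes} == set(toy.membership.values())

    def test_intermediate_focus_merges_subclosures(self, toy):
        fl = sf.validate_focus_level(toy, {"B", "F"})
        got = {n.union for n in sf.focus_closure(toy, fl).nodes}
        member = toy.membership
        sub_b = {n.union for n in sf.close_under_unions(
            {t: member[t] for t in "BCDE"}).nodes}
        sub_f = {n.union for n in sf.close_under_unions(
            {t: member[t] for t in "FE"}).nodes}
        assert got == sub_b | sub_f | {member["A"]}


class TestLocalLevels:
    def test_full_index_returns_initial_alpha(self):
        graph = figure4_graph()
        levels = sf.bretz_local_levels(graph, graph.names)
        assert levels == {"H1": pytest.approx(ALPHA / 2), "H2": 0.0,
                          "H3": pytest.approx(ALPHA / 2), "H4": 0.0}

    def test_figure4_removal_orders_agree(self):
        graph = figure4_graph()
        levels = sf.bretz_local_levels(graph, ["H2", "H4"])
        assert sum(levels.values()) <= ALPHA + 1e-12
        assert levels["H2"] == pytest.approx(ALPHA / 2)
        assert levels["H4"] == pytest.approx(ALPHA / 2)

    @pytest.mark.parametrize("r", [1, 2, 3, 4])
    def test_holm_closed_form(self, r):
        graph = holm_graph(5)
        index = [f"H{i}" for i in range(r)]
        levels = sf.bretz_local_levels(graph, index)
        for name in index:
            assert levels[name] == pytest.approx(ALPHA / r)

    def test_order_invariance_under_permuted_removal(self):
        # remove indices one at a time in random orders by chaining
        # single-index removals; final levels must agree
        rng = np.random.default_rng(4)
        graph = figure4_graph()
        from shortfocus.graphtest import SequentialState, reject_update

        def remove_in_order(order):
            state = SequentialState.from_graph(graph)
            for name in order:
                reject_update(state, graph.index(name))
            return state.alpha.copy()

        ref = remove_in_order(["H1", "H3"])
        assert remove_in_order(["H3", "H1"]) == pytest.approx(ref)

    def test_monotonicity_of_levels(self):
        # H_I ⊂ H_J (I ⊃ J here): each shared hypothesis's level can only
        # grow as more hypotheses are removed
        rng = np.random.default_rng(6)
        for _ in range(20):
            dag = random_nested_dag(rng, max_terms=6)
            fl = sf.validate_focus_level(dag, dag.roots())
            graph = sf.build_sfl_graph(dag, fl, ALPHA)
            names = list(graph.names)
            big = [n for n in names if rng.random() < 0.7] or names[:1]
            small = [n for n in big if rng.random() < 0.6] or big[:1]
            lv_small = sf.bretz_local_levels(graph, small)
            lv_big = sf.bretz_local_levels(graph, big)
            for n in small:
                assert lv_small[n] >= lv_big[n] - 1e-12


def closed_test_pvalue_rules(p, alpha=ALPHA):
    """Hand-coded closed-test rejections for the partially nested example.

    Implements the printed rules directly: p_H1=p1, p_H3=p3,
    p_H2=max(p1,p2), p_H4=max(p3,p4), p_Hij=min(1, 2p_Hi, 2p_Hj); an
    elementary hypothesis is rejected when its own closed-test p-value
    and those of all intersections implying it fall below α."""
    p1, p2, p3, p4 = p
    ph = {
        "H1": p1, "H3": p3,
        "H2": max(p1, p2), "H4": max(p3, p4),
    }
    for i in ("H1", "H2"):
        for j in ("H3", "H4"):
            ph[i + j[1]] = min(1.0, 2 * ph[i], 2 * ph[j])
    rejected = set()
    if ph["H13"] < alpha and ph["H14"] < alpha and ph["H1"] < alpha:
        rejected.add("H1")
    if ph["H13"] < alpha and ph["H14"] < alpha and ph["H23"] < alpha \
            and ph["H24"] < alpha and ph["H2"] < alpha:
        rejected.add("H2")
    if ph["H13"] < alpha and ph["H23"] < alpha and ph["H3"] < alpha:
        rejected.add("H3")
    if ph["H13"] < alpha and ph["H23"] < alpha and ph["H14"] < alpha \
            and ph["H24"] < alpha and ph["H4"] < alpha:
        rejected.add("H4")
    return rejected


class TestClosedTestOracle:
    def test_all_p_one_rejects_nothing(self):
        res = sf.closed_test_oracle(figure4_graph(), nested_pair_family(),
                                    {"H1": 1, "H2": 1, "H3": 1, "H4": 1})
        assert res.rejected == frozenset()
        assert all(v == 1.0 for v in res.adjusted_p.values())

    def test_root_rejected_when_twice_min_below_alpha(self):
        p = {"H1": 0.015, "H2": 0.9, "H3": 0.8, "H4": 0.9}
        res = sf.closed_test_oracle(figure4_graph(), nested_pair_family(), p)
        root = frozenset({"a1", "a2", "b1", "b2"})
        node = next(n for n in res.node_table
                    if set(n["minimal_index"]) == {"H1", "H3"})
        assert node["rejected"]  # 2·min(p1,p3) = 0.03 < α
        assert "H1" in res.rejected

    def test_matches_printed_closed_test_rules(self):
        # the decision flow of the worked example, over a grid of p-vectors
        rng = np.random.default_rng(12)
        graph = figure4_graph()
        fam = nested_pair_family()
        for _ in range(300):
            p = rng.uniform(0.001, 0.5, 4) ** 2 + 1e-4
            got = sf.closed_test_oracle(
                graph, fam, dict(zip(fam.names, p))).rejected
            assert got == closed_test_pvalue_rules(p)

    def test_empty_intersection_flagged(self):
        fam = nested_pair_family()
        with pytest.raises(ValueError, match="empty"):
            sf.closed_test_oracle(figure4_graph(), fam,
                                  {"H1": 0.5, "H2": 0.5, "H3": 0.5, "H4": 0.5},
                                  nonempty_check=lambda union: len(union) < 3)


class TestMinimalGeneratingSubset:
    def test_drops_dominated_and_redundant(self):
        ev = {"A": frozenset("xyz"), "B": frozenset("x"), "C": frozenset("w")}
        assert minimal_generating_subset(["A", "B", "C"], ev) == ("A", "C")

    def test_exhaustive_prefers_smallest(self):
        ev = {"A": frozenset("xy"), "B": frozenset("yz"), "C": frozenset("xyz")}
        assert minimal_generating_subset(["A", "B", "C"], ev) == ("C",)
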