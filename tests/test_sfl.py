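"""The Short Focus Level procedure: graph construction, cascade, invariants."""

import numpy as np
import pytest

import shortfocus as sf
from shortfocus.sfl import run_bottomup, run_topdown

from conftest import (
    holm_adjust_oracle,
    holm_oracle,
    random_nested_dag,
    random_pvalues,
)

ALPHA = 0.05


class TestBuildGraph:
    def test_toy_intermediate_focus_weights(self, toy):
        fl = sf.validate_focus_level(toy, {"B", "F"})
        g = sf.build_sfl_graph(toy, fl, ALPHA)
        i = {n: k for k, n in enumerate(g.names)}
        assert g.alpha[i["B"]] == pytest.approx(0.025)
        assert g.alpha[i["F"]] == pytest.approx(0.025)
        for child in "CDE":
            assert g.weights[i["B"], i[child]] == pytest.approx(1 / 3)
        assert g.weights[i["F"], i["E"]] == pytest.approx(1.0)
        for terminal in "CDE":
            assert g.weights[i[terminal], i["B"]] == pytest.approx(0.5)
            assert g.weights[i[terminal], i["F"]] == pytest.approx(0.5)

    def test_single_term_keeps_full_level(self):
        dag = sf.build_dag([], {"X": {"g"}})
        fl = sf.validate_focus_level(dag, {"X"})
        g = sf.build_sfl_graph(dag, fl, ALPHA)
        assert g.alpha == pytest.approx([ALPHA])
        assert np.all(g.weights == 0)

    def test_root_focus_leaves_recycle_fully(self, nested14):
        fl = sf.validate_focus_level(nested14, nested14.roots())
        g = sf.build_sfl_graph(nested14, fl, ALPHA)
        i = {n: k for k, n in enumerate(g.names)}
        assert g.alpha[i["GO:01"]] == pytest.approx(ALPHA)
        for leaf in nested14.leaves():
            assert g.weights[i[leaf], i["GO:01"]] == pytest.approx(1.0)

    def test_terminal_focus_terms_recycle_to_each_other(self):
        dag = sf.build_dag([], {"X": {"x"}, "Y": {"y"}, "Z": {"z"}})
        fl = sf.validate_focus_level(dag, dag.terms)
        g = sf.build_sfl_graph(dag, fl, ALPHA)
        off_diag = g.weights[~np.eye(3, dtype=bool)]
        assert off_diag == pytest.approx(np.full(6, 0.5))

    def test_regularity_always_holds(self):
        rng = np.random.default_rng(2)
        for _ in range(25):
            dag = random_nested_dag(rng)
            fl = sf.validate_focus_level(dag, dag.roots())
            sf.validate_regularity(sf.build_sfl_graph(dag, fl, ALPHA))


class TestTopdown:
    def test_chain_cascades_full_level(self):
        dag = sf.build_dag([("R", "K")], {"R": {"x", "y"}, "K": {"y"}})
        fl = sf.validate_focus_level(dag, {"R"})
        td = run_topdown(dag, fl, {"R": 0.01, "K": 0.04}, ALPHA)
        assert td.rejected == {"R", "K"}

    def test_child_untestable_while_parent_stands(self):
        dag = sf.build_dag([("R", "K")], {"R": {"x", "y"}, "K": {"y"}})
        fl = sf.validate_focus_level(dag, {"R"})
        td = run_topdown(dag, fl, {"R": 0.2, "K": 0.001}, ALPHA)
        assert td.rejected == frozenset()

    def test_escrowed_mass_released_when_branch_becomes_redundant(self, toy):
        # F's mass passes through its (unrejected, redundant) offspring to
        # B: B must be tested at the full α once F is out
        fl = sf.validate_focus_level(toy, {"B", "F"})
        p = {"B": 0.04, "F": 0.01, "C": 0.9, "D": 0.9, "E": 0.9}
        assert run_topdown(toy, fl, p, ALPHA).rejected == {"B", "F"}

    def test_missing_pvalue_raises(self, toy):
        fl = sf.validate_focus_level(toy, {"B", "F"})
        with pytest.raises(ValueError, match="missing p-values"):
            run_topdown(toy, fl, {"B": 0.01}, ALPHA)

    def test_oracle_equivalence_on_toy(self, toy):
        fl = sf.validate_focus_level(toy, {"B", "F"})
        graph = sf.build_sfl_graph(toy, fl, ALPHA)
        fam = sf.HypothesisFamily.from_dag(toy, graph.names)
        rng = np.random.default_rng(42)
        for _ in range(200):
            p = random_pvalues(rng, graph.names)
            shortcut = run_topdown(toy, fl, p, ALPHA).rejected
            oracle = sf.closed_test_oracle(graph, fam, p).rejected
            assert shortcut == oracle


class TestBottomup:
    def test_ancestor_inherits_focus_rejection(self, toy):
        fl = sf.validate_focus_level(toy, {"B", "F"})
        bu = run_bottomup(toy, fl, {"B": 0.01, "F": 0.2}, ALPHA, {"B"})
        assert bu.rejected == {"A"}

    def test_no_focus_rejections_no_ancestors(self, toy):
        fl = sf.validate_focus_level(toy, {"B", "F"})
        bu = run_bottomup(toy, fl, {"B": 0.5, "F": 0.2}, ALPHA, set())
        assert bu.rejected == frozenset()

    def test_holm_inheritance_adjusted_p(self, toy):
        fl = sf.validate_focus_level(toy, {"B", "F"})
        bu = run_bottomup(toy, fl, {"B": 0.01, "F": 0.2}, ALPHA, {"B"})
        # Holm over (0.01, 0.2) -> (0.02, 0.2); A inherits the minimum
        assert bu.adjusted_p["A"] == pytest.approx(0.02)


class TestSFL:
    def test_all_p_one(self, toy):
        fl = sf.validate_focus_level(toy, {"B", "F"})
        res = sf.sfl(toy, fl, {t: 1.0 for t in toy.terms}, ALPHA)
        assert res.rejected == frozenset()
        assert all(v == 1.0 for v in res.adjusted_p.values())

    def test_offspring_free_focus_reduces_to_holm(self):
        mem = {f"T{i}": {f"x{i}"} for i in range(6)}
        dag = sf.build_dag([], mem)
        fl = sf.validate_focus_level(dag, dag.terms)
        rng = np.random.default_rng(11)
        for _ in range(40):
            p = {t: float(v) for t, v in zip(dag.terms, rng.uniform(1e-3, 1, 6))}
            res = sf.sfl(dag, fl, p, ALPHA)
            assert res.rejected == holm_oracle(p, ALPHA)
            holm = holm_adjust_oracle(p)
            for t in dag.terms:
                assert res.adjusted_p[t] == pytest.approx(holm[t], abs=2e-5)

    def test_rejection_iff_adjusted_below_alpha(self, toy):
        fl = sf.validate_focus_level(toy, {"B", "F"})
        rng = np.random.default_rng(17)
        for _ in range(20):
            p = random_pvalues(rng, toy.terms)
            res = sf.sfl(toy, fl, p, ALPHA)
            for t in res.terms:
                if res.adjusted_p[t] < ALPHA - 1e-5:
                    assert t in res.rejected
                if res.adjusted_p[t] > ALPHA + 1e-5:
                    assert t not in res.rejected

    def test_coherence_on_random_dags(self):
        rng = np.random.default_rng(23)
        for _ in range(30):
            dag = random_nested_dag(rng)
            p = random_pvalues(rng, dag.terms)
            res = sf.sfl(dag, None, p, ALPHA, adjusted=False)
            for t in res.rejected:
                assert dag.ancestors[t] <= res.rejected

    def test_adjusted_p_monotone_along_ancestry(self):
        rng = np.random.default_rng(29)
        for _ in range(10):
            dag = random_nested_dag(rng)
            p = random_pvalues(rng, dag.terms)
            res = sf.sfl(dag, None, p, ALPHA)
            for parent, child in dag.edges:
                assert res.adjusted_p[child] >= res.adjusted_p[parent] - 1e-9

    def test_rejection_sets_nested_in_alpha(self):
        rng = np.random.default_rng(31)
        dag = random_nested_dag(rng)
        p = random_pvalues(rng, dag.terms)
        prev = frozenset()
        for a in (0.01, 0.05, 0.2, 0.5):
            cur = sf.sfl(dag, None, p, a, adjusted=False).rejected
            assert prev <= cur
            prev = cur

    def test_holm_dominance_at_focus(self, toy):
        # anything plain Holm on the focus p-values rejects, the full
        # procedure rejects too: recycling only ever adds threshold mass
        fl = sf.validate_focus_level(toy, {"B", "F"})
        rng = np.random.default_rng(37)
        for _ in range(100):
            p = random_pvalues(rng, toy.terms)
            res = sf.sfl(toy, fl, p, ALPHA, adjusted=False)
            holm = holm_oracle({t: p[t] for t in fl.focus}, ALPHA)
            assert holm <= res.rejected

    def test_focus_stub_raises(self, toy):
        with pytest.raises(NotImplementedError):
            sf.suggest_focus_level(toy)


class TestOracleEquivalenceRandom:
    def test_shortcut_equals_closed_test_on_random_structures(self):
        """The executable consonance claim: on random nested families the
        sequential shortcut's rejection set equals the brute-force
        restricted closed test's, draw for draw."""
        rng = np.random.default_rng(101)
        draws = 0
        while draws < 200:
            dag = random_nested_dag(rng)
            fl = sf.validate_focus_level(dag, dag.roots())
            graph = sf.build_sfl_graph(dag, fl, ALPHA)
            fam = sf.HypothesisFamily.from_dag(dag, graph.names)
            p = random_pvalues(rng, graph.names)
            shortcut = run_topdown(dag, fl, p, ALPHA).rejected
            oracle = sf.closed_test_oracle(graph, fam, p).rejected
            assert shortcut == oracle
            draws += 1
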