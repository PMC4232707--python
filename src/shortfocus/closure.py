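"""Brute-force closed-testing machinery for restricted hypotheses.

Hypotheses are encoded by *evidence sets*: H_i implies H_j exactly when
evidence(i) ⊇ evidence(j).  For self-contained gene-set nulls the evidence
set is simply the term's gene membership — the null on a superset of genes
implies the null on any subset.  An intersection hypothesis H_I is encoded
by the union of evidence sets over I, so two index sets represent the same
intersection iff their unions coincide.  This is what makes GO-style
families *restricted*: the deduplicated closure has fewer than 2^m − 1
members.

The closed test here is the slow-but-transparent reference: every distinct
closure element is tested by a weighted Bonferroni test whose local levels
α_i(I) are derived from an (α, G) graph by removing all indices outside I
with the graphical update rule.  The sequential shortcut elsewhere in the
package must agree with it exactly; that equivalence is the executable
content of the consonance theorem the Short Focus Level rests on.

Practical ceiling: closure enumeration is exponential in the number of
generators and is intended for ≤ 20 sets (oracle duties), not for
genome-scale graphs.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from typing import Iterable, Mapping, Sequence

import numpy as np

from .dag import GeneSetDAG, FocusLevel
from .graphtest import (
    ALPHA_FLOOR,
    P_TOL,
    SequentialState,
    WeightedTestGraph,
    reject_update,
)

__all__ = [
    "HypothesisFamily",
    "ClosureNode",
    "ClosureGraph",
    "OracleResult",
    "close_under_unions",
    "close_family",
    "focus_closure",
    "bretz_local_levels",
    "closed_test_oracle",
    "minimal_generating_subset",
]


@dataclass(frozen=True)
class HypothesisFamily:
    """Elementary hypotheses with their evidence-set encoding."""

    names: tuple[str, ...]
    evidence: Mapping[str, frozenset]

    @classmethod
    def from_sets(cls, sets: Mapping[str, Iterable]) -> "HypothesisFamily":
        ev = {str(k): frozenset(v) for k, v in sets.items()}
        for k, s in ev.items():
            if not s:
                raise ValueError(f"hypothesis {k!r} has empty evidence set")
        return cls(tuple(sorted(ev)), ev)

    @classmethod
    def from_dag(cls, dag: GeneSetDAG, terms: Iterable[str] | None = None) -> "HypothesisFamily":
        terms = tuple(sorted(terms)) if terms is not None else dag.terms
        return cls(terms, {t: dag.membership[t] for t in terms})

    def implies(self, i: str, j: str) -> bool:
        return self.evidence[i] >= self.evidence[j]


@dataclass(frozen=True)
class ClosureNode:
    """One distinct closure element.

    ``union`` is the canonical evidence-set union, ``minimal_index`` the
    smallest generating index set (cardinality, then lexicographic), and
    ``n_generating`` how many index subsets map to this element.
    """

    union: frozenset
    minimal_index: tuple[str, ...]
    n_generating: int


@dataclass(frozen=True)
class ClosureGraph:
    """Deduplicated closure with provenance; nodes sorted deterministically."""

    nodes: tuple[ClosureNode, ...]
    generators: tuple[str, ...]

    @property
    def k_closure(self) -> int:
        return len(self.nodes)

    def implication_edges(self) -> tuple[tuple[int, int], ...]:
        """(i, j) pairs where node i implies node j (union_i ⊋ union_j)."""
        out = []
        for i, a in enumerate(self.nodes):
            for j, b in enumerate(self.nodes):
                if i != j and a.union > b.union:
                    out.append((i, j))
        return tuple(out)


def _enumerate_closure(sets: Mapping[str, frozenset]) -> ClosureGraph:
    names = tuple(sorted(sets))
    if len(names) > 20:
        raise ValueError(f"closure enumeration limited to 20 generators, got {len(names)}")
    seen: dict[frozenset, list] = {}
    # increasing subset size => the first index set reaching a union is a
    # minimal one, and lexicographic combinations fix the tie-break
    for r in range(1, len(names) + 1):
        for idx in combinations(names, r):
            u = frozenset().union(*(sets[i] for i in idx))
            rec = seen.get(u)
            if rec is None:
                seen[u] = [idx, 1]
            else:
                rec[1] += 1
    nodes = tuple(
        ClosureNode(u, rec[0], rec[1])
        for u, rec in sorted(seen.items(), key=lambda kv: (-len(kv[0]), sorted(kv[0])))
    )
    return ClosureGraph(nodes, names)


def close_under_unions(sets: Mapping[str, Iterable]) -> ClosureGraph:
    """All distinct unions over nonempty subcollections of ``sets``."""
    canon = {str(k): frozenset(v) for k, v in sets.items()}
    if not canon:
        raise ValueError("need at least one set")
    for k, s in canon.items():
        if not s:
            raise ValueError(f"set {k!r} is empty")
    return _enumerate_closure(canon)


def antichain_node_count(sets: Mapping[str, Iterable]) -> int:
    """Size of the closed graph when nodes are antichains, not unions.

    Closed-graph constructions used by focus-level implementations merge
    a subcollection into its inclusion-maximal members (an antichain) but
    do not notice when two different antichains produce the same gene
    content, so the node count they report is the number of nonempty
    antichains of the inclusion order.  This matches those published
    graph sizes and upper-bounds :func:`close_under_unions`'s count of
    truly distinct unions; the two coincide whenever the sets are in
    generic position (each set holding a gene absent from all sets not
    containing it).
    """
    canon = {str(k): frozenset(v) for k, v in sets.items()}
    names = sorted(canon)
    count = 0
    for r in range(1, len(names) + 1):
        for idx in combinations(names, r):
            if all(
                not (canon[a] <= canon[b] or canon[b] <= canon[a])
                for a, b in combinations(idx, 2)
            ):
                count += 1
    return count


def close_family(family: HypothesisFamily) -> ClosureGraph:
    """Intersection closure of a hypothesis family, deduplicated.

    Under the evidence encoding, intersecting hypotheses unions their
    evidence sets, so this is :func:`close_under_unions` of the evidence
    sets.  For an unrestricted family the count is 2^m − 1.
    """
    return _enumerate_closure(dict(family.evidence))


def focus_closure(dag: GeneSetDAG, focus: FocusLevel) -> ClosureGraph:
    """Focus-level closure: per-focus-term subgraph closures, merged.

    Each focus term together with its offspring is closed under unions
    separately; the closed subgraphs are merged with deduplication and the
    ancestors of the focus level are kept as singleton nodes above.  When
    the focus level is the set of roots this coincides with the full union
    closure of the focus-and-below system.
    """
    merged: dict[frozenset, ClosureNode] = {}
    for f in sorted(focus.focus):
        below = {f} | set(dag.offspring[f])
        sub = close_under_unions({t: dag.membership[t] for t in sorted(below)})
        for node in sub.nodes:
            prev = merged.get(node.union)
            if prev is None or (len(node.minimal_index), node.minimal_index) < (
                len(prev.minimal_index), prev.minimal_index
            ):
                count = node.n_generating if prev is None else prev.n_generating
                merged[node.union] = ClosureNode(node.union, node.minimal_index, count)
    for t in focus.terms_in("ancestor"):
        u = dag.membership[t]
        if u not in merged:
            merged[u] = ClosureNode(u, (t,), 1)
    nodes = tuple(sorted(merged.values(), key=lambda n: (-len(n.union), sorted(n.union))))
    gens = tuple(sorted(set(dag.terms)))
    return ClosureGraph(nodes, gens)


def minimal_generating_subset(
    members: Sequence[str], evidence: Mapping[str, frozenset], exhaustive_limit: int = 15
) -> tuple[str, ...]:
    """Smallest subset of ``members`` whose evidence union equals the whole.

    Only inclusion-maximal members can take part.  Among those, the exact
    minimum-cardinality subset (lexicographic tie-break) is found by
    enumeration when at most ``exhaustive_limit`` candidates remain;
    beyond that a greedy irredundant reduction is used.  The same helper
    backs both the sequential shortcut and the closed-test oracle so the
    two routes share tie-breaks.
    """
    members = sorted(members)
    target = frozenset().union(*(evidence[t] for t in members))
    # inclusion-maximal members (first of any duplicated evidence set)
    maximal = []
    for t in members:
        dominated = any(
            evidence[o] > evidence[t] or (evidence[o] == evidence[t] and o < t)
            for o in members if o != t
        )
        if not dominated:
            maximal.append(t)
    if len(maximal) <= exhaustive_limit:
        for r in range(1, len(maximal) + 1):
            for idx in combinations(maximal, r):
                if frozenset().union(*(evidence[t] for t in idx)) == target:
                    return idx
    # greedy irredundant: drop any member covered by the union of the rest
    keep = list(maximal)
    for t in list(keep):
        rest = [o for o in keep if o != t]
        if rest and evidence[t] <= frozenset().union(*(evidence[o] for o in rest)):
            keep.remove(t)
    return tuple(keep)


def bretz_local_levels(graph: WeightedTestGraph, index_set: Iterable[str]) -> dict[str, float]:
    """Local levels α_i(I): remove every hypothesis outside I from (α, G).

    Removal uses the graphical update rule; the result does not depend on
    the removal order (asserted by property tests, not recomputed here).
    Returns {name: α_i(I)} for i ∈ I, with Σ ≤ α.
    """
    wanted = {str(i) for i in index_set}
    unknown = wanted - set(graph.names)
    if unknown:
        raise ValueError(f"unknown hypotheses in index set: {sorted(unknown)}")
    if not wanted:
        raise ValueError("index set must be nonempty")
    state = SequentialState.from_graph(graph)
    for j, name in enumerate(graph.names):
        if name not in wanted:
            reject_update(state, j)
    return {name: float(state.alpha[graph.index(name)]) for name in sorted(wanted)}


@dataclass(frozen=True)
class OracleResult:
    """Closed-test oracle output."""

    rejected: frozenset[str]
    adjusted_p: Mapping[str, float]
    node_table: tuple[dict, ...]


def closed_test_oracle(
    graph: WeightedTestGraph,
    family: HypothesisFamily,
    p: Mapping[str, float],
    nonempty_check=None,
) -> OracleResult:
    """Full closed test with graph-derived weighted Bonferroni local tests.

    Every distinct closure element H_I is tested at the local levels
    α_j(I) evaluated at its minimal generating index set: H_I is rejected
    iff p_j ≤ α_j(I) for some j ∈ I.  An elementary hypothesis is rejected
    iff every closure element implying it is rejected, and its adjusted
    p-value is the max over those elements of the element's weighted
    Bonferroni p-value min_j p_j·α/α_j(I).

    ``nonempty_check(union) -> bool`` may be supplied when the evidence
    encoding cannot itself witness that intersections are nonempty (they
    always are for gene-set nulls); a False return raises.
    """
    if set(graph.names) != set(family.names):
        raise ValueError("graph and family must index the same hypotheses")
    pv = {str(k): float(v) for k, v in p.items()}
    missing = set(family.names) - set(pv)
    if missing:
        raise ValueError(f"missing p-values for: {sorted(missing)}")

    closure = close_family(family)
    alpha = graph.alpha_total
    node_table = []
    node_rejected: dict[frozenset, bool] = {}
    node_p: dict[frozenset, float] = {}
    for node in closure.nodes:
        if nonempty_check is not None and not nonempty_check(node.union):
            raise ValueError(f"closure element with empty intersection hypothesis: {node.minimal_index}")
        # evaluate levels at the minimal generating subset of the node's
        # full index class, via the same helper the sequential shortcut
        # uses, so the two routes share tie-breaking
        index_class = [t for t in family.names if family.evidence[t] <= node.union]
        idx = minimal_generating_subset(index_class, family.evidence)
        levels = bretz_local_levels(graph, idx)
        rej = any(
            levels[j] > ALPHA_FLOOR and pv[j] <= levels[j] + P_TOL for j in idx
        )
        ratios = [pv[j] * alpha / levels[j] for j in idx if levels[j] > ALPHA_FLOOR]
        padj_node = min([1.0] + ratios) if ratios else 1.0
        padj_node = min(1.0, padj_node)
        node_rejected[node.union] = rej
        node_p[node.union] = padj_node
        node_table.append({
            "minimal_index": idx,
            "levels": levels,
            "rejected": rej,
            "p_node": padj_node,
        })

    rejected = set()
    adjusted = {}
    for h in family.names:
        ev = family.evidence[h]
        implying = [u for u in node_rejected if u >= ev]
        if all(node_rejected[u] for u in implying):
            rejected.add(h)
        adjusted[h] = max(node_p[u] for u in implying)
    return OracleResult(frozenset(rejected), adjusted, tuple(node_table))
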