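"""Gene-set DAGs, focus levels, and their set-theoretic relations.

A :class:`GeneSetDAG` holds a collection of gene sets (GO-style terms)
arranged by parent→child edges, where every child's membership is a subset
of each parent's ("true-path" consistency).  The null hypothesis attached
to a term is the self-contained one — *no gene in the set is differentially
expressed* — so a parent's null implies each child's null, and the nulls on
the graph are logically nested.  All downstream procedures (sequential
graphical testing, closed-testing oracles) consume the frozen relation
tables computed here once at construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx

__all__ = [
    "GeneSetDAG",
    "FocusLevel",
    "DagValidationError",
    "FocusLevelError",
    "build_dag",
    "validate_focus_level",
    "infer_hasse",
    "atoms",
]


class DagValidationError(ValueError):
    """The edge list / memberships do not form a valid gene-set DAG."""


class FocusLevelError(ValueError):
    """A proposed focus level violates FL1 or FL2.

    Attributes
    ----------
    rule : str
        Which requirement failed: ``"FL1"``, ``"FL2"`` or ``"terms"``.
    offenders : tuple
        The offending terms (FL1: (focus, offspring-focus) pairs;
        FL2: uncovered terms).
    """

    def __init__(self, rule: str, offenders, message: str):
        super().__init__(message)
        self.rule = rule
        self.offenders = tuple(offenders)


@dataclass(frozen=True)
class GeneSetDAG:
    """Immutable gene-set DAG with cached transitive relations.

    Parameters are normally supplied through :func:`build_dag`, which
    validates acyclicity, nonempty memberships and subset consistency.
    """

    terms: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]
    membership: Mapping[str, frozenset[str]]
    children: Mapping[str, tuple[str, ...]] = field(repr=False)
    parents: Mapping[str, tuple[str, ...]] = field(repr=False)
    ancestors: Mapping[str, frozenset[str]] = field(repr=False)
    offspring: Mapping[str, frozenset[str]] = field(repr=False)

    @property
    def m(self) -> int:
        """Number of terms."""
        return len(self.terms)

    def n_children(self, term: str) -> int:
        return len(self.children[term])

    def roots(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if not self.parents[t])

    def leaves(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if not self.children[t])

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for s in self.membership.values():
            out |= s
        return frozenset(out)

    def subgraph_edges(self, keep: Iterable[str]) -> tuple[tuple[str, str], ...]:
        """Edges of the DAG with both endpoints in ``keep``."""
        keep = set(keep)
        return tuple((a, b) for a, b in self.edges if a in keep and b in keep)


@dataclass(frozen=True)
class FocusLevel:
    """A validated focus level: an antichain F covering the rest of the DAG.

    ``strata`` maps every term to one of ``"ancestor"``, ``"focus"``,
    ``"offspring"``; the three classes partition the term set.
    """

    focus: frozenset[str]
    strata: Mapping[str, str]

    @property
    def m_f(self) -> int:
        return len(self.focus)

    def terms_in(self, stratum: str) -> tuple[str, ...]:
        return tuple(sorted(t for t, s in self.strata.items() if s == stratum))


def _relations(terms, edges):
    g = nx.DiGraph()
    g.add_nodes_from(terms)
    g.add_edges_from(edges)
    if not nx.is_directed_acyclic_graph(g):
        cycle = [a for a, _ in nx.find_cycle(g)]
        raise DagValidationError(f"edge relation contains a cycle: {' -> '.join(cycle + [cycle[0]])}")
    children = {t: tuple(sorted(g.successors(t))) for t in terms}
    parents = {t: tuple(sorted(g.predecessors(t))) for t in terms}
    offspring = {t: frozenset(nx.descendants(g, t)) for t in terms}
    ancestors = {t: frozenset(nx.ancestors(g, t)) for t in terms}
    return children, parents, ancestors, offspring


def build_dag(
    edges: Iterable[tuple[str, str]],
    membership: Mapping[str, Iterable[str]],
    propagate: bool = False,
) -> GeneSetDAG:
    """Assemble and validate a :class:`GeneSetDAG`.

    Parameters
    ----------
    edges
        Parent→child pairs; endpoints must be keys of ``membership``.
    membership
        Term → iterable of gene identifiers (opaque strings).
    propagate
        If true, each gene annotated to a term is first copied to all of
        the term's ancestors (the GO true-path rule), so subset validation
        cannot fail.

    Raises
    ------
    DagValidationError
        On a cycle, an empty membership, an unknown edge endpoint, or
        (with ``propagate=False``) a child set not contained in a parent.
    """
    edges = tuple((str(a), str(b)) for a, b in edges)
    member = {str(t): frozenset(map(str, gs)) for t, gs in membership.items()}
    terms = tuple(sorted(member))
    known = set(terms)
    for a, b in edges:
        if a not in known or b not in known:
            raise DagValidationError(f"edge ({a}, {b}) references a term with no membership entry")
    children, parents, ancestors, offspring = _relations(terms, edges)

    if propagate:
        prop = {t: set(member[t]) for t in terms}
        for t in terms:
            for anc in ancestors[t]:
                prop[anc] |= member[t]
        member = {t: frozenset(s) for t, s in prop.items()}

    for t in terms:
        if not member[t]:
            raise DagValidationError(f"term {t!r} has empty gene membership")
    for a, b in edges:
        if not member[b] <= member[a]:
            extra = sorted(member[b] - member[a])[:5]
            raise DagValidationError(
                f"true-path violation on edge ({a}, {b}): child genes {extra} missing from parent"
                " (pass propagate=True to propagate annotations upward)"
            )
    return GeneSetDAG(terms, edges, member, children, parents, ancestors, offspring)


def validate_focus_level(dag: GeneSetDAG, focus: Iterable[str]) -> FocusLevel:
    """Check FL1/FL2 for a proposed focus level and assign strata.

    FL1: no focus term is an offspring of another focus term.
    FL2: every non-focus term is an ancestor or an offspring of some
    focus term.

    Raises
    ------
    FocusLevelError
        Naming the violated rule and the offending terms.
    """
    f = frozenset(str(t) for t in focus)
    if not f:
        raise FocusLevelError("terms", (), "focus level must be nonempty")
    unknown = sorted(f - set(dag.terms))
    if unknown:
        raise FocusLevelError("terms", unknown, f"unknown focus terms: {unknown}")

    fl1 = sorted(
        (a, b) for a in f for b in f if b in dag.offspring[a]
    )
    if fl1:
        pairs = ", ".join(f"({a}, {b})" for a, b in fl1)
        raise FocusLevelError("FL1", fl1, f"FL1 violated: focus contains offspring of focus terms: {pairs}")

    strata: dict[str, str] = {}
    uncovered = []
    for t in dag.terms:
        if t in f:
            strata[t] = "focus"
        elif dag.offspring[t] & f:
            # t has a focus term below it
            strata[t] = "ancestor"
        elif dag.ancestors[t] & f:
            strata[t] = "offspring"
        else:
            uncovered.append(t)
    if uncovered:
        raise FocusLevelError(
            "FL2", uncovered,
            f"FL2 violated: terms neither ancestors nor offspring of the focus level: {sorted(uncovered)}",
        )
    return FocusLevel(f, strata)


def infer_hasse(membership: Mapping[str, Iterable[str]]) -> GeneSetDAG:
    """Build a DAG from memberships alone via the covering relation of ⊂.

    An edge i→j is drawn iff membership(j) ⊂ membership(i) with no third
    set strictly between.  Two terms with identical memberships are
    rejected: they would carry indistinguishable hypotheses.
    """
    member = {str(t): frozenset(map(str, gs)) for t, gs in membership.items()}
    for t, s in member.items():
        if not s:
            raise DagValidationError(f"term {t!r} has empty gene membership")
    by_content: dict[frozenset, list[str]] = {}
    for t, s in member.items():
        by_content.setdefault(s, []).append(t)
    dups = sorted(tuple(sorted(v)) for v in by_content.values() if len(v) > 1)
    if dups:
        raise DagValidationError(f"duplicate gene sets (identical membership): {dups}")

    terms = sorted(member)
    order = nx.DiGraph()
    order.add_nodes_from(terms)
    for a in terms:
        for b in terms:
            if a != b and member[b] < member[a]:
                order.add_edge(a, b)
    hasse = nx.transitive_reduction(order)
    return build_dag(tuple(sorted(hasse.edges())), member)


def atoms(membership: Mapping[str, Iterable[str]]) -> dict[frozenset[str], frozenset[str]]:
    """Partition the gene universe by membership signature.

    Returns a mapping {signature (frozenset of terms) → block (frozenset of
    genes)}: two genes share a block iff they belong to exactly the same
    terms.  Every term's membership is a disjoint union of blocks; the
    number of blocks bounds the closure size at 2^k − 1.
    """
    member = {str(t): frozenset(map(str, gs)) for t, gs in membership.items()}
    for t, s in member.items():
        if not s:
            raise DagValidationError(f"term {t!r} has empty gene membership")
    sig: dict[str, set[str]] = {}
    for t, genes in member.items():
        for g in genes:
            sig.setdefault(g, set()).add(t)
    blocks: dict[frozenset[str], set[str]] = {}
    for g, ts in sig.items():
        blocks.setdefault(frozenset(ts), set()).add(g)
    return {k: frozenset(v) for k, v in blocks.items()}
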