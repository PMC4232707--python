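"""Readers and writers for the formats the tool touches.

OBO ontologies (is_a skeleton via obonet), two-column gene→term
annotation TSVs, GMT gene-set files, parent→child edge lists, per-gene or
per-set p-value TSVs, a results TSV, and a DOT rendering of the
significant subgraph.  All writers are deterministic (stable sort keys).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

from .dag import GeneSetDAG, build_dag
from .sfl import SFLResult

__all__ = [
    "DagSkeleton",
    "read_obo",
    "read_annotations",
    "read_gmt",
    "read_edge_list",
    "read_pvalues",
    "prune_small_sets",
    "write_results",
    "read_results",
    "write_dot",
]


@dataclass(frozen=True)
class DagSkeleton:
    """Terms and is_a edges from an ontology, before annotation."""

    terms: tuple[str, ...]
    edges: tuple[tuple[str, str], ...]  # parent -> child
    names: Mapping[str, str]


def read_obo(path, namespace: str | None = "biological_process") -> DagSkeleton:
    """Parse an OBO file into a term/edge skeleton.

    Only ``is_a`` relationships are kept (``part_of`` and other typedefs
    are ignored); obsolete terms are skipped; ``namespace=None`` disables
    the namespace filter.
    """
    import obonet

    try:
        graph = obonet.read_obo(path, ignore_obsolete=True)
    except Exception as exc:  # pragma: no cover - passthrough context
        raise ValueError(f"failed to parse OBO file {path}: {exc}") from exc

    def keep(node_data) -> bool:
        if namespace is None:
            return True
        return node_data.get("namespace", namespace) == namespace

    terms = sorted(t for t, d in graph.nodes(data=True) if keep(d))
    termset = set(terms)
    names = {t: graph.nodes[t].get("name", t) for t in terms}
    edges = []
    # obonet stores edges child -> parent keyed by relationship type
    for child, parent, rel in graph.edges(keys=True):
        if rel == "is_a" and child in termset and parent in termset:
            edges.append((parent, child))
    return DagSkeleton(tuple(terms), tuple(sorted(set(edges))), names)


def read_annotations(path, skeleton: DagSkeleton, propagate: bool = True) -> GeneSetDAG:
    """Fill a skeleton with gene memberships from a two-column TSV.

    Columns: gene id, term id (no header).  Unknown term ids are skipped
    with a single warning carrying the count; terms that end up with no
    genes are dropped (their edges re-routed transitively).  An empty
    result is an error.
    """
    df = pd.read_csv(path, sep="\t", header=None, names=["gene", "term"], dtype=str)
    known = set(skeleton.terms)
    member: dict[str, set[str]] = {t: set() for t in skeleton.terms}
    skipped = 0
    for gene, term in df.itertuples(index=False):
        if term in known:
            member[term].add(gene)
        else:
            skipped += 1
    if skipped:
        warnings.warn(f"skipped {skipped} annotation rows with unknown term ids")
    # propagate before dropping empty terms so inherited genes count
    if propagate:
        g = nx.DiGraph(skeleton.edges)
        g.add_nodes_from(skeleton.terms)
        for t in list(member):
            if member[t]:
                for anc in nx.ancestors(g, t):
                    member[anc] |= member[t]
    keep = {t for t, s in member.items() if s}
    if not keep:
        raise ValueError(f"no usable annotations in {path}")
    edges = _reroute_edges(skeleton.terms, skeleton.edges, keep)
    return build_dag(edges, {t: member[t] for t in keep})


def read_gmt(path) -> dict[str, frozenset[str]]:
    """GMT reader: one line per set (name, description, genes...)."""
    out: dict[str, frozenset[str]] = {}
    for i, line in enumerate(Path(path).read_text().splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) < 3:
            raise ValueError(f"{path}:{i}: GMT lines need name, description and ≥1 gene")
        out[parts[0]] = frozenset(g for g in parts[2:] if g)
    if not out:
        raise ValueError(f"no gene sets in {path}")
    return out


def read_edge_list(path) -> tuple[tuple[str, str], ...]:
    """Two-column TSV of parent, child term ids (no header)."""
    df = pd.read_csv(path, sep="\t", header=None, names=["parent", "child"], dtype=str)
    return tuple(df.itertuples(index=False, name=None))


def read_pvalues(path, key: str = "id") -> dict[str, float]:
    """TSV with a header row: first column identifier, second p-value."""
    df = pd.read_csv(path, sep="\t")
    ids, ps = df.columns[0], df.columns[1]
    out = dict(zip(df[ids].astype(str), df[ps].astype(float)))
    bad = [k for k, v in out.items() if not 0 <= v <= 1]
    if bad:
        raise ValueError(f"p-values outside [0,1] for: {bad[:5]}")
    return out


def _reroute_edges(terms, edges, keep: set[str]) -> tuple[tuple[str, str], ...]:
    """Covering relation of reachability restricted to kept terms."""
    g = nx.DiGraph(edges)
    g.add_nodes_from(terms)
    closure = nx.DiGraph()
    closure.add_nodes_from(keep)
    for t in keep:
        for d in nx.descendants(g, t):
            if d in keep:
                closure.add_edge(t, d)
    reduced = nx.transitive_reduction(closure)
    return tuple(sorted(reduced.edges()))


def prune_small_sets(dag: GeneSetDAG, min_size: int = 5) -> GeneSetDAG:
    """Drop terms with fewer than ``min_size`` genes, re-routing edges.

    The default threshold of 5 genes mirrors common gene-set-analysis
    practice of excluding tiny sets whose combined p-values are unstable.
    """
    keep = {t for t in dag.terms if len(dag.membership[t]) >= min_size}
    if not keep:
        raise ValueError(f"no terms with at least {min_size} genes remain")
    edges = _reroute_edges(dag.terms, dag.edges, keep)
    return build_dag(edges, {t: dag.membership[t] for t in keep})


def results_frame(result: SFLResult, names: Mapping[str, str] | None = None) -> pd.DataFrame:
    df = result.to_frame()
    if names:
        df.insert(1, "name", [names.get(t, "") for t in df["term"]])
    return df


def write_results(result: SFLResult, path, names: Mapping[str, str] | None = None) -> None:
    """Write the per-term results table as TSV with a commented header."""
    df = results_frame(result, names)
    with open(path, "w") as fh:
        fh.write(f"# shortfocus results; alpha={result.alpha}; "
                 f"focus={','.join(sorted(result.focus.focus))}\n")
        df.to_csv(fh, sep="\t", index=False)


def read_results(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")


def write_dot(result: SFLResult, dag: GeneSetDAG, path,
              names: Mapping[str, str] | None = None) -> None:
    """Render the significant subgraph as a DOT file.

    Only rejected terms and their induced edges appear; nodes are
    numbered in sorted term order with a legend in node tooltips.  By
    coherence every shown node's DAG ancestors are shown too, so the
    subgraph is upward closed.
    """
    rejected = sorted(result.rejected)
    number = {t: i + 1 for i, t in enumerate(rejected)}
    lines = ["digraph significant {", '  node [shape=box];']
    for t in rejected:
        label = f"{number[t]}"
        tip = names.get(t, t) if names else t
        adj = result.adjusted_p.get(t, float("nan"))
        lines.append(f'  "{t}" [label="{label}", tooltip="{tip} (adj p={adj:.3g})"];')
    keep = set(rejected)
    for a, b in sorted(dag.edges):
        if a in keep and b in keep:
            lines.append(f'  "{a}" -> "{b}";')
    lines.append("}")
    Path(path).write_text("\n".join(lines) + "\n")
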