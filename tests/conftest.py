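"""Shared fixtures: toy DAGs, random nested families, Holm helpers."""

from __future__ import annotations

import numpy as np
import pytest

import shortfocus as sf


@pytest.fixture(scope="session")
def toy():
    """6-term toy DAG in generic position (A root; B, F mid; C, D, E leaves)."""
    return sf.toy_dag()


@pytest.fixture(scope="session")
def nested14():
    """The 14-term nested system and its inferred DAG."""
    return sf.nested14_dag()


def holm_oracle(p: dict[str, float], alpha: float) -> set[str]:
    """Direct step-down Holm rejections, independent of any library."""
    items = sorted(p.items(), key=lambda kv: kv[1])
    m = len(items)
    rejected: set[str] = set()
    for rank, (name, pv) in enumerate(items):
        if pv <= alpha / (m - rank):
            rejected.add(name)
        else:
            break
    return rejected


def holm_adjust_oracle(p: dict[str, float]) -> dict[str, float]:
    """Direct Holm adjusted p-values from the step-down definition."""
    items = sorted(p.items(), key=lambda kv: kv[1])
    m = len(items)
    out, running = {}, 0.0
    for rank, (name, pv) in enumerate(items):
        running = max(running, min(1.0, (m - rank) * pv))
        out[name] = running
    return out


def random_nested_dag(rng: np.random.Generator, max_terms: int = 7) -> sf.GeneSetDAG:
    """Random DAG with generic-position memberships.

    Every term gets a private gene plus the genes of its offspring, so
    distinct subcollections always have distinct unions and every term's
    evidence is strictly larger than each child's.
    """
    k = int(rng.integers(2, max_terms + 1))
    names = [f"T{i}" for i in range(k)]
    edges = []
    for j in range(1, k):
        # at least one parent among earlier nodes keeps the graph connected
        n_par = 1 + int(rng.random() < 0.3)
        for parent in rng.choice(j, size=min(n_par, j), replace=False):
            edges.append((names[int(parent)], names[j]))
    membership = {t: {f"priv_{t}"} for t in names}
    return sf.build_dag(edges, membership, propagate=True)


def random_pvalues(rng: np.random.Generator, terms, low: float = 1e-4) -> dict[str, float]:
    # squared uniforms concentrate mass near zero so rejections happen often
    return {t: float(max(low, x)) for t, x in zip(terms, rng.uniform(0, 1, len(terms)) ** 2)}
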