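"""Synthetic studies for power and error-rate evaluation.

Two generators mirror the package's reference simulation designs:

* **Gaussian phenotype study** (:func:`simulate_gaussian_design`) — a continuous
  phenotype Y ~ N(0,1) and a 20×100 expression matrix of N(0,1) variates
  on a fixed 14-term nested gene-set system (:data:`NESTED14_RANGES`);
  three designated terms receive signal by adding r·Y to their genes'
  columns, making their ancestors significant by inheritance.
* **RNA-seq counts study** (:func:`simulate_counts_design`) — a two-group design
  with negative-binomial counts, variance μ + μ²/d (d = 10), on the
  6-term toy DAG with randomized gene assignments; randomly chosen leaf
  sets get fold changes 2^β with β ~ Poisson(λ).  Per-gene control means
  are drawn from a log-normal stand-in for an empirical RNA-seq mean
  distribution (median ≈ 20 counts).

:func:`power_harness` runs any generator × set-test × procedure triple
for ``n_reps`` replicates and reports per-term rejection rates, an FWER
estimate over true nulls, and Monte-Carlo standard errors, reproducibly
from one seed via spawned per-replicate streams.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd

from .dag import GeneSetDAG, build_dag, infer_hasse
from .settests import ExpressionStudy, global_test

__all__ = [
    "NESTED14_RANGES",
    "GAUSSIAN_SIGNAL_TERMS",
    "GAUSSIAN_TRUTH_TERMS",
    "nested14_memberships",
    "nested14_dag",
    "toy_memberships",
    "toy_dag",
    "GaussianDesignConfig",
    "CountsDesignConfig",
    "simulate_gaussian_design",
    "simulate_counts_design",
    "power_harness",
]

#: gene index ranges (inclusive) of the 14-term nested system; genes are
#: labeled g001..g100
NESTED14_RANGES: dict[str, tuple[int, int]] = {
    "GO:01": (1, 100),
    "GO:02": (1, 40),
    "GO:03": (21, 60),
    "GO:04": (61, 100),
    "GO:05": (1, 10),
    "GO:06": (11, 20),
    "GO:07": (21, 40),
    "GO:08": (41, 50),
    "GO:09": (51, 60),
    "GO:10": (61, 80),
    "GO:11": (71, 90),
    "GO:12": (81, 100),
    "GO:13": (72, 79),
    "GO:14": (82, 89),
}

#: terms that receive direct signal, and the full set of truly associated
#: terms (signal terms plus their ancestors, by inheritance)
GAUSSIAN_SIGNAL_TERMS: tuple[str, ...] = ("GO:06", "GO:07", "GO:13")
GAUSSIAN_TRUTH_TERMS: frozenset[str] = frozenset(
    ["GO:01", "GO:02", "GO:03", "GO:04", "GO:06", "GO:07", "GO:10", "GO:11", "GO:13"]
)


def _gene(i: int) -> str:
    return f"g{i:03d}"


def nested14_memberships() -> dict[str, frozenset[str]]:
    """The 14 nested gene sets over genes g001..g100."""
    return {
        t: frozenset(_gene(i) for i in range(lo, hi + 1))
        for t, (lo, hi) in NESTED14_RANGES.items()
    }


def nested14_dag() -> GeneSetDAG:
    """The 14-term DAG, inferred from the memberships' inclusion order."""
    return infer_hasse(nested14_memberships())


def toy_memberships() -> dict[str, frozenset[str]]:
    """A generic-position realization of the 6-term toy DAG.

    A is the root with children B and F; B covers C, D, E; F covers E.
    Each parent holds a private gene absent from all of its children, so
    all unions over subcollections in the closure are distinct.
    """
    e = {"gE"}
    c = {"gC"}
    d = {"gD"}
    b = {"gB"} | c | d | e
    f = {"gF"} | e
    a = {"gA"} | b | f
    return {k: frozenset(v) for k, v in
            {"A": a, "B": b, "C": c, "D": d, "E": e, "F": f}.items()}


def toy_dag() -> GeneSetDAG:
    edges = [("A", "B"), ("A", "F"), ("B", "C"), ("B", "D"), ("B", "E"), ("F", "E")]
    return build_dag(edges, toy_memberships())


@dataclass(frozen=True)
class GaussianDesignConfig:
    """Gaussian-phenotype study configuration (reference design values)."""

    n: int = 20
    r: float = 0.5
    n_reps: int = 1000
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.r <= 1.0:
            raise ValueError(f"effect r must be in [0, 1], got {self.r}")
        if self.n < 3:
            raise ValueError("need n >= 3 samples")


def simulate_gaussian_design(
    config: GaussianDesignConfig | None = None,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> tuple[ExpressionStudy, GeneSetDAG, frozenset[str]]:
    """Draw one Gaussian-phenotype study on the 14-term system.

    Returns (study, dag, truth): Y ~ N(0,1)^n, X ~ N(0,1)^{n×100} with
    r·Y added to the columns of the genes of the signal terms; truth is
    empty when r = 0.
    """
    config = config or GaussianDesignConfig(**kwargs)
    rng = rng or np.random.default_rng(config.seed)
    genes = tuple(_gene(i) for i in range(1, 101))
    y = rng.standard_normal(config.n)
    x = rng.standard_normal((config.n, 100))
    member = nested14_memberships()
    if config.r > 0:
        signal_genes = sorted(frozenset().union(*(member[t] for t in GAUSSIAN_SIGNAL_TERMS)))
        cols = [genes.index(g) for g in signal_genes]
        x[:, cols] += config.r * y[:, None]
    truth = GAUSSIAN_TRUTH_TERMS if config.r > 0 else frozenset()
    return ExpressionStudy(x, y, genes), nested14_dag(), truth


def _default_mean_sampler(rng: np.random.Generator, size: int) -> np.ndarray:
    # log-normal stand-in for an empirical RNA-seq per-gene mean
    # distribution: median ~e^3 ≈ 20 counts, long right tail
    return rng.lognormal(mean=3.0, sigma=1.5, size=size)


@dataclass(frozen=True)
class CountsDesignConfig:
    """Two-group RNA-seq counts study configuration.

    ``effect_rate`` is the Poisson rate λ of the per-gene log2 fold
    changes in the chosen significant leaf sets; ``dispersion`` is the
    NB scale d in Var = μ + μ²/d.
    """

    n: int = 20
    max_set_size: int = 10
    effect_rate: float = 1.0
    dispersion: float = 10.0
    n_signal_leaves: int = 1
    mean_sampler: Callable[[np.random.Generator, int], np.ndarray] = field(
        default=_default_mean_sampler
    )
    seed: int = 0

    def __post_init__(self):
        if self.dispersion <= 0:
            raise ValueError("dispersion d must be > 0")
        if self.effect_rate < 0:
            raise ValueError("effect rate λ must be ≥ 0")
        if self.n < 4:
            raise ValueError("need n ≥ 4 so both groups can have ≥ 2 samples")


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, d: float, n_cols: int) -> np.ndarray:
    # NB(mu, mu + mu^2/d): shape d, success prob d/(d+mu)
    p = d / (d + mu)
    return rng.negative_binomial(d, p[:, None], size=(mu.size, n_cols)).T


def _assign_leaf_genes(rng: np.random.Generator, max_size: int) -> dict[str, set[str]]:
    """Random overlapping gene assignment to leaf sets C, D, E.

    Genes shared by j leaves occur with probability ∝ 2^−j: wide sharing
    is discouraged, pairwise sharing allowed more often."""
    leaves = ["C", "D", "E"]
    sizes = {t: int(rng.integers(1, max_size + 1)) for t in leaves}
    weights = np.array([2.0 ** -j for j in (1, 2, 3)])
    weights /= weights.sum()
    member: dict[str, set[str]] = {t: set() for t in leaves}
    gene_no = 0
    while any(len(member[t]) < sizes[t] for t in leaves):
        j = int(rng.choice([1, 2, 3], p=weights))
        short = [t for t in leaves if len(member[t]) < sizes[t]]
        take = [t for t in rng.choice(leaves, size=min(j, len(leaves)), replace=False)
                if t in short]
        if not take:
            take = [short[0]]
        gene_no += 1
        g = f"s{gene_no:04d}"
        for t in take:
            member[t].add(g)
    return member


def simulate_counts_design(
    config: CountsDesignConfig | None = None,
    rng: np.random.Generator | None = None,
    **kwargs,
) -> tuple[ExpressionStudy, GeneSetDAG, frozenset[str]]:
    """Draw one two-group NB counts study on the randomized 6-term toy DAG.

    Group sizes are Binomial(n, 1/2), redrawn until both groups have at
    least two samples.  Control counts are NB(μ_i, μ_i + μ_i²/d); in the
    randomly chosen significant leaf sets the treatment means are
    2^{β_i}·μ_i with β_i ~ Poisson(λ).  Truth holds every term containing
    at least one gene with a nonzero fold change (empty when λ = 0,
    where all fold changes are 2⁰).
    """
    config = config or CountsDesignConfig(**kwargs)
    rng = rng or np.random.default_rng(config.seed)

    while True:
        n_trt = int(rng.binomial(config.n, 0.5))
        if 2 <= n_trt <= config.n - 2:
            break
    y = np.array([0] * (config.n - n_trt) + [1] * n_trt, dtype=float)

    member = {t: set(s) for t, s in _assign_leaf_genes(rng, config.max_set_size).items()}
    gene_no = sum(len(s) for s in member.values())
    for parent, kids in (("B", ("C", "D", "E")), ("F", ("E",)), ("A", ("B", "F"))):
        fresh = int(rng.integers(1, config.max_set_size + 1))
        own = {f"p{parent}{i:04d}" for i in range(fresh)}
        member[parent] = own | set().union(*(member[k] for k in kids))
        gene_no += fresh
    edges = [("A", "B"), ("A", "F"), ("B", "C"), ("B", "D"), ("B", "E"), ("F", "E")]
    dag = build_dag(edges, member)

    genes = tuple(sorted(dag.genes()))
    mu = np.asarray(config.mean_sampler(rng, len(genes)), dtype=float)
    mu = np.maximum(mu, 1e-3)

    leaves = ["C", "D", "E"]
    n_sig = min(config.n_signal_leaves, len(leaves))
    signal_leaves = sorted(rng.choice(leaves, size=n_sig, replace=False)) if n_sig else []
    beta = np.zeros(len(genes))
    if config.effect_rate > 0 and signal_leaves:
        sig_genes = set().union(*(member[t] for t in signal_leaves))
        idx = [i for i, g in enumerate(genes) if g in sig_genes]
        beta[idx] = rng.poisson(config.effect_rate, size=len(idx))
    mu_trt = (2.0 ** beta) * mu

    ctrl = _nb_draw(rng, mu, config.dispersion, config.n - n_trt)
    trt = _nb_draw(rng, mu_trt, config.dispersion, n_trt)
    x = np.vstack([ctrl, trt]).astype(float)

    # a term's self-contained null is false iff it contains at least one
    # gene with a nonzero fold change — overlap can make non-chosen
    # leaves genuinely non-null, and a chosen leaf can stay null when all
    # its Poisson draws are zero
    de_genes = {g for g, b in zip(genes, beta) if b > 0}
    truth = frozenset(t for t in dag.terms if dag.membership[t] & de_genes)
    return ExpressionStudy(x, y, genes), dag, truth


def default_set_test(
    study: ExpressionStudy, genes, rng: np.random.Generator
) -> float:
    return global_test(study, genes, method="asymptotic")


def power_harness(
    generator: Callable[[np.random.Generator], tuple[ExpressionStudy, GeneSetDAG, frozenset[str]]],
    set_test: Callable[[ExpressionStudy, frozenset, np.random.Generator], float],
    procedure: Callable[[GeneSetDAG, Mapping[str, float], float], frozenset[str]],
    n_reps: int,
    alpha: float = 0.05,
    seed: int = 0,
) -> tuple[pd.DataFrame, float, float]:
    """Monte-Carlo power/FWER harness.

    ``generator(rng)`` yields a (study, dag, truth) triple; ``set_test``
    maps (study, gene set, rng) to a raw p-value; ``procedure`` maps
    (dag, per-term p, alpha) to the rejected term set.  Returns
    (per-term table with truth/power/MC-SE, FWER estimate, its MC-SE),
    where the FWER is the fraction of replicates rejecting at least one
    true-null term.  Identical seeds give identical output (per-replicate
    spawned streams, order-independent).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be ≥ 1")
    streams = np.random.SeedSequence(seed).spawn(n_reps)
    rej_counts: dict[str, int] = {}
    truth_counts: dict[str, int] = {}
    fwer_hits = 0
    for ss in streams:
        rng = np.random.default_rng(ss)
        study, dag, truth = generator(rng)
        p = {t: set_test(study, dag.membership[t], rng) for t in dag.terms}
        rejected = procedure(dag, p, alpha)
        for t in dag.terms:
            rej_counts[t] = rej_counts.get(t, 0) + (t in rejected)
            truth_counts[t] = truth_counts.get(t, 0) + (t in truth)
        if any(t not in truth for t in rejected):
            fwer_hits += 1
    rows = []
    for t in sorted(rej_counts):
        pw = rej_counts[t] / n_reps
        rows.append({
            "term": t,
            # fraction of replicates in which the term was truly non-null
            # (0 or 1 for fixed-truth designs)
            "truth": truth_counts[t] / n_reps,
            "power": pw,
            "mc_se": float(np.sqrt(pw * (1 - pw) / n_reps)),
        })
    fwer = fwer_hits / n_reps
    fwer_se = float(np.sqrt(fwer * (1 - fwer) / n_reps))
    return pd.DataFrame(rows), fwer, fwer_se
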