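"""Self-contained gene-set p-value machinery.

Two families of tests are provided, both addressing the null *no gene in
the set is differentially expressed*:

* combination of per-gene p-values (Stouffer, Fisher), for use when an
  upstream per-gene analysis (e.g. a count-model differential-expression
  fit) has already been run;
* a global score test of association between an expression submatrix and
  a phenotype, in the style of Goeman's Global Test, with an exact
  normal-theory null and a permutation alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
from scipy import integrate, stats

__all__ = [
    "ExpressionStudy",
    "stouffer_combine",
    "fisher_combine",
    "global_test",
    "combine_per_set",
    "correlation_gene_pvalues",
]

#: clipping bounds keeping normal quantiles finite
_P_CLIP = 1e-15


def _clip_p(p: np.ndarray) -> np.ndarray:
    if np.any((p <= 0) | (p >= 1)):
        warnings.warn(
            "p-values at exactly 0 or 1 clipped to [1e-15, 1-1e-15]",
            stacklevel=3,
        )
        p = np.clip(p, _P_CLIP, 1 - _P_CLIP)
    return p


def stouffer_combine(p: Iterable[float], method: str = "sqrt_k") -> float:
    """Stouffer's Z combination of one-sided per-gene p-values.

    Each p_i becomes a standard-normal upper-tail quantile Z_i; the
    default combines them as Z* = ΣZ_i/√k (null-uniform).  The variant
    ``method="mean"`` takes the tail probability beyond the plain mean
    Z-score instead — it is not uniform under the null and exists for
    fidelity experiments only.
    """
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    p = _clip_p(p)
    z = stats.norm.isf(p)
    if method == "sqrt_k":
        z_star = z.sum() / np.sqrt(len(z))
    elif method == "mean":
        z_star = z.mean()
    else:
        raise ValueError(f"unknown method {method!r}")
    return float(stats.norm.sf(z_star))


def fisher_combine(p: Iterable[float]) -> float:
    """Fisher's combination: −2Σln p against chi-square with 2k df."""
    p = np.asarray(list(p), dtype=float)
    if p.size == 0:
        raise ValueError("need at least one p-value")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    p = _clip_p(p)
    stat = -2.0 * np.log(p).sum()
    return float(stats.chi2.sf(stat, 2 * len(p)))


def combine_per_set(
    gene_p: Mapping[str, float],
    membership: Mapping[str, Iterable[str]],
    combiner: str = "stouffer",
    min_size: int = 1,
) -> dict[str, float]:
    """Combine per-gene p-values into per-set p-values.

    Sets whose intersection with the p-value keys has fewer than
    ``min_size`` genes are dropped.
    """
    fn = {"stouffer": stouffer_combine, "fisher": fisher_combine}[combiner]
    out = {}
    for term, genes in membership.items():
        ps = [gene_p[g] for g in sorted(set(genes)) if g in gene_p]
        if len(ps) >= min_size and ps:
            out[term] = fn(ps)
    return out


@dataclass(frozen=True)
class ExpressionStudy:
    """Expression matrix (samples × genes) with a phenotype vector.

    ``x`` is real-valued or counts; ``y`` continuous or two-group coded
    numerically.  Gene identifiers index the columns.
    """

    x: np.ndarray
    y: np.ndarray
    genes: tuple[str, ...]

    def __post_init__(self):
        x = np.asarray(self.x, dtype=float)
        y = np.asarray(self.y, dtype=float)
        if x.ndim != 2:
            raise ValueError("x must be 2-d (samples × genes)")
        if y.shape != (x.shape[0],):
            raise ValueError(f"y length {y.shape} does not match {x.shape[0]} samples")
        if len(self.genes) != x.shape[1]:
            raise ValueError("gene names must match the number of columns")
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)
        object.__setattr__(self, "genes", tuple(map(str, self.genes)))

    @property
    def n(self) -> int:
        return self.x.shape[0]

    @property
    def m_genes(self) -> int:
        return self.x.shape[1]

    def columns(self, genes: Iterable[str]) -> np.ndarray:
        idx = {g: i for i, g in enumerate(self.genes)}
        wanted = sorted(set(map(str, genes)) & set(self.genes))
        if not wanted:
            raise ValueError("gene set has empty intersection with the study's genes")
        return self.x[:, [idx[g] for g in wanted]]


def correlation_gene_pvalues(
    study: "ExpressionStudy", two_sided: bool = True
) -> dict[str, float]:
    """Per-gene Pearson-correlation t-test p-values against the phenotype.

    The workhorse single-gene screen feeding the p-value combiners: for
    each gene the sample correlation with Y is converted to a t statistic
    on n−2 degrees of freedom.  ``two_sided=False`` gives upper-tail
    p-values (positive association), the orientation Stouffer's
    consensus combination expects.
    """
    y = study.y
    yc = y - y.mean()
    m2 = float(yc @ yc)
    if m2 <= 0:
        raise ValueError("phenotype is constant; association undefined")
    x = study.x - study.x.mean(axis=0, keepdims=True)
    denom = np.sqrt((x ** 2).sum(axis=0) * m2)
    r = np.where(denom > 0, (x.T @ yc) / np.maximum(denom, 1e-300), 0.0)
    r = np.clip(r, -1 + 1e-12, 1 - 1e-12)
    n = study.n
    t = r * np.sqrt((n - 2) / (1 - r ** 2))
    if two_sided:
        p = 2 * stats.t.sf(np.abs(t), n - 2)
    else:
        p = stats.t.sf(t, n - 2)
    return dict(zip(study.genes, map(float, p)))


def _weighted_chisq_sf_at_zero(weights: np.ndarray) -> float:
    """P(Σ w_i Z_i² ≥ 0) for independent standard normals, via Imhof.

    Numerical inversion of the characteristic function; exact up to
    quadrature error.  Used at the origin only, where the integrand does
    not oscillate."""
    w = np.asarray(weights, dtype=float)
    w = w[np.abs(w) > 1e-12 * max(1.0, np.abs(w).max())]
    if w.size == 0:
        return 1.0
    if np.all(w >= 0):
        return 1.0
    if np.all(w <= 0):
        return 0.0
    scale = np.abs(w).max()
    w = w / scale

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(w * u))
        rho = np.exp(0.25 * np.sum(np.log1p((w * u) ** 2)))
        return np.sin(theta) / (u * rho)

    val, _ = integrate.quad(integrand, 0.0, np.inf, limit=200)
    return float(min(1.0, max(0.0, 0.5 + val / np.pi)))


def global_test(
    study: ExpressionStudy,
    geneset: Iterable[str],
    method: str = "asymptotic",
    n_perm: int = 999,
    seed: int | np.random.Generator | None = None,
) -> float:
    """Global score test of association between a gene set and a phenotype.

    The statistic is Q = (Y−Ȳ)' R (Y−Ȳ) with R = X_S X_S'/|S| on the
    column-centered expression submatrix X_S of the set.  Large Q means
    the phenotype aligns with expression variation inside the set.

    ``method="asymptotic"`` evaluates the exact null of the studentized
    statistic under Gaussian phenotypes: with λ the nontrivial
    eigenvalues of the centered R and q = Q(n−1)/Σ(Y−Ȳ)², the p-value is
    P(Σ(λ_i − q/(n−1))·χ²₁ ≥ 0), computed by numerical inversion.  This
    is scale-free and finite-sample exact for normal Y; for two-group Y
    it is an approximation and ``method="permutation"`` (p = (b+1)/(B+1)
    over B random phenotype permutations) is available.
    """
    if study.n < 3:
        raise ValueError("need at least 3 samples")
    y = study.y
    yc = y - y.mean()
    m2 = float(yc @ yc)
    if m2 <= 0:
        raise ValueError("phenotype is constant; association undefined")
    xs = study.columns(geneset)
    xs = xs - xs.mean(axis=0, keepdims=True)  # column-center
    k = xs.shape[1]
    q_obs = float(yc @ (xs @ (xs.T @ yc))) / k

    if method == "asymptotic":
        n = study.n
        r = (xs @ xs.T) / k
        # centered R restricted to the (n-1)-dim mean-zero subspace:
        # columns already centered, so HRH = R; drop one structural zero
        # eigenvalue belonging to the constant direction
        lam = np.linalg.eigvalsh(r)
        lam = np.sort(lam)[::-1][: n - 1]
        ratio = q_obs * (n - 1) / m2
        return _weighted_chisq_sf_at_zero(lam - ratio / (n - 1))
    if method == "permutation":
        rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
        b = 0
        for _ in range(n_perm):
            yp = rng.permutation(yc)
            q = float(yp @ (xs @ (xs.T @ yp))) / k
            if q >= q_obs - 1e-12:
                b += 1
        return (b + 1) / (n_perm + 1)
    raise ValueError(f"unknown method {method!r}")
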