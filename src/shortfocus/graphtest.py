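"""Graphical weighted-Bonferroni sequentially rejective testing.

A :class:`WeightedTestGraph` is the pair (α, G): local thresholds α_i over
m hypotheses with Σα_i ≤ α, and edge weights g_ij (0 ≤ g_ij ≤ 1, g_ii = 0,
row sums ≤ 1) that say how a rejected hypothesis's threshold is passed on.
Rejecting hypothesis j updates the remaining graph by

    α_ℓ ← α_ℓ + α_j · g_jℓ
    g_ℓk ← (g_ℓk + g_ℓj · g_jk) / (1 − g_ℓj · g_jℓ)   (0 if denominator ≤ 0)

and the procedure repeats while some unrejected hypothesis satisfies
p_j ≤ α_j.  The final rejection set is invariant to the order in which
qualifying hypotheses are taken, and the procedure strongly controls the
familywise error rate at Σα_i.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "WeightedTestGraph",
    "SequentialState",
    "RegularityError",
    "validate_regularity",
    "reject_update",
    "sequential_reject",
]

#: slack for p ≤ α comparisons, so exact-boundary arithmetic does not
#: flip on float rounding
P_TOL = 1e-12
#: a local threshold below this is treated as exactly zero (untestable)
ALPHA_FLOOR = 1e-15


class RegularityError(ValueError):
    """The (α, G) pair violates a regularity condition."""


@dataclass(frozen=True)
class WeightedTestGraph:
    """The (α, G) pair over named hypotheses.

    ``alpha`` holds absolute local thresholds (not fractions of the
    overall level); ``alpha_total`` is the overall FWER level α.
    """

    names: tuple[str, ...]
    alpha: np.ndarray
    weights: np.ndarray
    alpha_total: float

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.asarray(self.alpha, dtype=float))
        object.__setattr__(self, "weights", np.asarray(self.weights, dtype=float))

    @property
    def m(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)


def validate_regularity(graph: WeightedTestGraph, tol: float = 1e-12) -> None:
    """Raise :class:`RegularityError` unless both regularity conditions hold.

    Condition 1: Σ α_i ≤ α.  Condition 2: 0 ≤ g_ij ≤ 1, g_ii = 0 and
    Σ_k g_ik ≤ 1 for every row i.  Sums are checked with tolerance ``tol``.
    """
    a, g = graph.alpha, graph.weights
    m = graph.m
    if a.shape != (m,) or g.shape != (m, m):
        raise RegularityError(f"shape mismatch: alpha {a.shape}, weights {g.shape}, m={m}")
    if np.any(a < -tol):
        raise RegularityError("condition 1: negative local threshold")
    if a.sum() > graph.alpha_total + tol:
        raise RegularityError(
            f"condition 1: sum of local thresholds {a.sum():.6g} exceeds alpha={graph.alpha_total}"
        )
    if np.any(g < -tol) or np.any(g > 1 + tol):
        i, j = np.argwhere((g < -tol) | (g > 1 + tol))[0]
        raise RegularityError(f"condition 2: weight g[{graph.names[i]},{graph.names[j]}] outside [0,1]")
    if np.any(np.abs(np.diag(g)) > tol):
        i = int(np.argmax(np.abs(np.diag(g))))
        raise RegularityError(f"condition 2: self-weight g_ii nonzero at {graph.names[i]}")
    rows = g.sum(axis=1)
    if np.any(rows > 1 + tol):
        i = int(np.argmax(rows))
        raise RegularityError(
            f"condition 2: row sum {rows[i]:.6g} exceeds 1 at {graph.names[i]}"
        )


@dataclass
class SequentialState:
    """Mutable state of the sequential procedure.

    ``alpha``/``weights`` are the current reduced graph (rows/columns of
    rejected hypotheses zeroed), ``rejected`` the cumulative rejection
    order S, and ``log`` an audit trail of threshold flows.
    """

    names: tuple[str, ...]
    alpha: np.ndarray
    weights: np.ndarray
    alpha_total: float
    rejected: list[int] = field(default_factory=list)
    log: list[dict] = field(default_factory=list)

    @classmethod
    def from_graph(cls, graph: WeightedTestGraph) -> "SequentialState":
        return cls(graph.names, graph.alpha.copy(), graph.weights.copy(), graph.alpha_total)

    @property
    def rejected_names(self) -> tuple[str, ...]:
        return tuple(self.names[i] for i in self.rejected)

    def active(self) -> np.ndarray:
        mask = np.ones(len(self.names), dtype=bool)
        mask[self.rejected] = False
        return mask

    def copy(self) -> "SequentialState":
        return SequentialState(
            self.names, self.alpha.copy(), self.weights.copy(), self.alpha_total,
            list(self.rejected), list(self.log),
        )


def reject_update(state: SequentialState, j: int) -> SequentialState:
    """Reject hypothesis ``j`` in place and redistribute its threshold.

    The caller is responsible for having established p_j ≤ α_j (or for
    performing a virtual removal during level computation).  Raises on a
    doubly rejected index.
    """
    if j in state.rejected:
        raise ValueError(f"hypothesis {state.names[j]} already rejected")
    a, g = state.alpha, state.weights
    flow = a[j] * g[j, :]
    # weight transfer: g_lk <- (g_lk + g_lj g_jk) / (1 - g_lj g_jl)
    denom = 1.0 - g[:, j] * g[j, :]  # per-row l: g_lj * g_jl
    numer = g + np.outer(g[:, j], g[j, :])
    safe = denom[:, None] > 0
    new_g = np.where(safe, numer / np.where(safe, denom[:, None], 1.0), 0.0)
    new_a = a + flow
    # zero out the rejected hypothesis
    new_a[j] = 0.0
    new_g[j, :] = 0.0
    new_g[:, j] = 0.0
    np.fill_diagonal(new_g, 0.0)
    np.clip(new_g, 0.0, 1.0, out=new_g)
    state.log.append({
        "rejected": state.names[j],
        "threshold": float(a[j]),
        "flow": {state.names[k]: float(flow[k]) for k in np.flatnonzero(flow > 0)},
    })
    state.alpha = new_a
    state.weights = new_g
    state.rejected.append(j)
    return state


def sequential_reject(
    graph: WeightedTestGraph,
    p: Sequence[float],
    eligible: Callable[[int, SequentialState], bool] | None = None,
) -> SequentialState:
    """Run the sequentially rejective procedure on (α, G).

    At each step, among unrejected, eligible hypotheses with p_j ≤ α_j,
    the one with the smallest p_j/α_j ratio (ties: smallest index) is
    rejected and the graph updated; the loop stops when none qualifies.
    With ``eligible=None`` this is the unrestricted graphical procedure.
    The final rejection set is order-invariant; the tie-break only fixes
    the audit log.
    """
    validate_regularity(graph)
    p = np.asarray(p, dtype=float)
    if p.shape != (graph.m,):
        raise ValueError(f"expected {graph.m} p-values, got shape {p.shape}")
    if np.any((p < 0) | (p > 1)):
        raise ValueError("p-values must lie in [0, 1]")
    state = SequentialState.from_graph(graph)
    while True:
        mask = state.active()
        cand = [
            j for j in np.flatnonzero(mask)
            if state.alpha[j] > ALPHA_FLOOR
            and p[j] <= state.alpha[j] + P_TOL
            and (eligible is None or eligible(int(j), state))
        ]
        if not cand:
            return state
        j = min(cand, key=lambda k: (p[k] / state.alpha[k], k))
        reject_update(state, int(j))
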