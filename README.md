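# shortfocus

Familywise-error-controlling multiple testing for gene-set collections
organized as a directed acyclic graph — the Gene Ontology being the
canonical case — via the **Short Focus Level** procedure: a sequentially
rejective, graph-based weighted-Bonferroni shortcut of the closed-testing
Focus Level method.

## Who this is for

Transcriptomics analysts (bulk or single-cell) who test hundreds or
thousands of GO-style gene sets for differential expression with
*self-contained* tests (null: no gene in the set is differentially
expressed) and want strong familywise error rate (FWER) control that
respects the logic of the graph: a parent set's null implies each child's
null, so the significant subgraph should be coherent — every rejected
term's ancestors rejected too.

## The procedure

Hypotheses `H_1, …, H_m` sit on the terms of a gene-set DAG.  The user
picks a **focus level** `F`: an antichain of terms (no focus term an
offspring of another, FL1) covering the rest of the graph (every other
term an ancestor or offspring of a focus term, FL2).  The default is the
root — the full top-down analysis.

A weighted test graph `(α, G)` is built over the focus-and-below terms:

* focus terms start with local thresholds `α_i = α/m_F`;
* each parent→child edge below the focus carries weight `g_ij = 1/m_i`
  (`m_i` = number of children of `i` in that subgraph);
* terminal terms recycle their thresholds to the `m_F` focus terms with
  weight `1/m_F` (a terminal focus term: to the others with
  `1/(m_F−1)`).

Rejecting `H_j` (when `p_j ≤ α_j`) redistributes its threshold,
`α_ℓ ← α_ℓ + α_j g_jℓ`, and rewires the weights,
`g_ℓk ← (g_ℓk + g_ℓj g_jk)/(1 − g_ℓj g_jℓ)`.  Because the gene-set nulls
are nested, the hypotheses are *restricted* (different index sets can
name the same intersection), and the procedure tests, each round, only
the minimal generating subset `I` of the remaining terms at levels
`α_j(I)` — the thresholds after redundant remaining terms are removed
from the graph.  This is exactly a shortcut of the closed test over the
union-closure of the gene sets with weighted Bonferroni local tests: the
package ships the brute-force closed test as an oracle and the test
suite asserts that the two reject identical terms, draw for draw.
Ancestors of the focus level are rejected bottom-up as soon as any
focus-level offspring is rejected.  Adjusted p-values are the smallest
overall `α` at which a term would be rejected (bisection).  The closure,
which grows exponentially and makes the classical closed test
intractable at the root focus, is never constructed.

Per-term p-values come from any self-contained test; the package
provides Stouffer and Fisher combination of per-gene p-values and a
global score test `Q = (Y−Ȳ)ᵀ X_S X_Sᵀ (Y−Ȳ)/|S|` with an exact
normal-theory null (and a permutation option).

## Worked example

`examples/01_toy_short_focus_level.py` runs the 6-term toy DAG (root A;
B and F in the middle; leaves C, D, E) with focus `{B, F}` at α = 0.05:

```
term   stratum  raw_p  adjusted_p  rejected
   A  ancestor  0.500    0.004001      True
   B     focus  0.002    0.004001      True
   C offspring  0.004    0.024000      True
   D offspring  0.500    1.000000     False
   E offspring  0.900    1.000000     False
   F     focus  0.010    0.016667      True

rejected at FWER 0.05: ['A', 'B', 'C', 'F']
```

B and F are tested Holm-style at α/2; both fall, so the ancestor A is
significant by inheritance (its adjusted p is the best of its focus
offspring).  C becomes testable only after its parent B falls and is
tested at threshold mass recycled down B's edges — its adjusted p of
0.024 is the smallest FWER level at which the whole cascade still
reaches it.  D and E survive, and the rejected set is upward-closed in
the DAG, as promised.

The other scripts in `examples/` show closure/atom counting, the two
simulation designs, and the per-gene → per-set → adjusted pipeline.  A
thin CLI (`shortfocus run | simulate | closure-count`) wraps the same
library calls for file-based workflows (OBO + annotation TSV, or edge
list + GMT).

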