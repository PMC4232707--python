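# Methods

## Model and assumptions

Each term of a gene-set DAG carries the self-contained null *no gene in
the set is differentially expressed*.  Two structural assumptions make
the graph part of the inference: a parent's null implies each child's
null (memberships are nested along edges — the "true-path" rule), and a
parent whose children partition it is null when all children are.  The
procedures here require only the first, which is guaranteed by
construction: `build_dag` validates child ⊆ parent (optionally
propagating annotations upward first), and `infer_hasse` derives the
edge set from strict inclusion directly.  Everything downstream treats
the DAG as frozen.

Implication is represented set-theoretically throughout: hypothesis
`H_i` implies `H_j` iff evidence(i) ⊇ evidence(j), with a gene-set
hypothesis's evidence being its membership.  Intersections of hypotheses
correspond to unions of evidence sets, which makes deduplication of the
closure — the defining feature of *restricted* hypothesis families — a
matter of comparing canonical frozensets.

## The sequential procedure

`build_sfl_graph` constructs the `(α, G)` pair described in the README.
`run_topdown` then iterates:

1. Let `M` be the unrejected focus-and-below terms and `I` the minimal
   generating subset of `M` (smallest subset with the same evidence
   union; only inclusion-maximal members can participate).
2. Compute local levels `α_j(I)` by removing every term of `M \ I` from
   the current graph with the standard update rule (*virtually* — the
   real state keeps them).  Removal order does not matter; the tests
   assert this rather than assume it.
3. Reject the qualifying `j ∈ I` (`p_j ≤ α_j(I)`) with the smallest
   `p_j/α_j(I)` (ties: lexicographic), apply the update to the real
   state, and repeat; stop when no member of `I` qualifies.

Step 2 is the design decision that required the most care.  A naive
reading — thresholds flow only on rejection, and a child simply waits
until its parents fall — strands threshold mass on never-rejected
offspring.  A worked two-focus example (focus `{B, F}`, `p_B = 0.04`,
`p_F = 0.01`, `α = 0.05`) shows the naive variant testing B at α/2 and
stopping, while the closed test over the union-closure rejects B at the
full α: once F falls, F's mass parked below it can reach B because B's
own offspring are *redundant* — they add nothing to the intersection
being tested — and removing redundant members is exactly what evaluating
a weighted Bonferroni test at the minimal index set means.  The
minimal-`I` evaluation restores that mass, makes the procedure dominate
plain Holm on the focus level, and is verified against the brute-force
closed test on hundreds of random structures (`closed_test_oracle`,
which shares the minimal-index helper so tie-breaks cannot diverge).
Both routes use the same boundary tolerance (`p ≤ α + 1e-12`) and treat
levels below `1e-15` as untestable zeros.

The minimal generating subset is found exactly (minimum cardinality,
lexicographic tie-break, enumerated over the inclusion-maximal
candidates) when at most 15 candidates remain, else by greedy
irredundant reduction.  For memberships in generic position — every term
holding a gene absent from the terms not containing it — the two rules
coincide and the subset is unique; the synthetic generators produce
generic-position systems for exactly this reason.

`run_bottomup` rejects a strict ancestor of the focus level iff one of
its focus-level offspring was rejected, and computes the classical
inheritance value: the minimum Holm-adjusted p over those offspring.

## Adjusted p-values

For focus-and-below terms, the adjusted p-value is
`inf {α' : the term is rejected at level α'}`, found by bisection to
`1e-6` (rejection sets are nested in `α'`, which the tests check, so
this is well defined; reported values are floored near `1e-6`
accordingly).  For ancestors, the package reports the minimum over focus
offspring of the offspring's *final* adjusted p rather than the raw Holm
inheritance value: threshold recycling can push a focus term's adjusted
p below its Holm value, and using the Holm number for the ancestor would
then break the two properties the output guarantees — adjusted p
nondecreasing from root to leaf, and rejected ⟺ adjusted p ≤ α.  Since
the procedure dominates Holm at the focus (a tested property), the
reported ancestor value is never larger than the classical one.

## Closure accounting

`close_under_unions`/`close_family` enumerate distinct unions with
content deduplication, keeping one minimal generating index set per
node; the count is ≤ 2^m − 1 with equality iff the family is
unrestricted.  `antichain_node_count` reports the size of the closed
graph under the other convention in circulation — nodes identified by
their irredundant generating antichain, without noticing content-equal
unions of incomparable sets — which is what closure-building
implementations that only merge comparable sets produce.  The two counts
agree on generic-position systems (14 for the toy graph) and differ on
the 14-term reference system (383 distinct unions vs 574 antichain
nodes, 11 atoms bounding both by 2^11 − 1).  Enumeration is intended for
oracle duty and is capped at 20 generators.

## Set-level tests

**Stouffer** (default): `Z* = Σ Φ⁻¹(1−p_i)/√k`, upper tail.  Inputs are
one-sided p-values in a common direction.  The plain-mean variant
(`method="mean"`, tail beyond `mean(Z)`) is not null-uniform and exists
only for fidelity experiments.  **Fisher**: `−2Σ ln p_i` on `χ²_{2k}`.
Both clip inputs to `[1e-15, 1−1e-15]` (with a warning) to keep
quantiles finite.  `correlation_gene_pvalues` supplies the per-gene
screen (Pearson correlation t-tests) for simulation pipelines.

**Global score test**: `Q = (Y−Ȳ)ᵀ R (Y−Ȳ)` with `R = X_S X_Sᵀ/|S|` on
the column-centered submatrix.  The asymptotic p-value uses the exact
finite-sample null of the studentized ratio under Gaussian phenotypes:
with `λ` the n−1 nontrivial eigenvalues of the doubly centered `R` and
`q = Q(n−1)/Σ(Y−Ȳ)²`, `p = P(Σ (λ_i − q/(n−1)) χ²₁ ≥ 0)`, evaluated by
numerical inversion of the characteristic function at the origin (where
the integrand does not oscillate).  This form is scale-free — no
variance estimate enters — and its first two moments coincide with the
permutation moments of the studentized statistic.  For two-group
phenotypes it is an approximation; `method="permutation"` gives
`(b+1)/(B+1)` over B random phenotype permutations.  Calibration is
asserted empirically: uniform null p-values (Kolmogorov–Smirnov) and
asymptotic–permutation agreement within 0.02 on a fixed fixture.

## Synthetic designs

**Gaussian phenotype design** (`simulate_gaussian_design`): `Y ~ N(0,1)^n`,
`X ~ N(0,1)^{n×100}` on a fixed 14-term nested system; the genes of
three designated terms receive `+ r·Y`, so those terms and their
ancestors are truly associated.  Defaults `n = 20`, `r = 0.5`.  It
emulates phenotype-correlated expression with known per-term truth; it
does **not** emulate gene–gene correlation beyond the shared signal,
heteroscedasticity, or realistic effect-size heterogeneity, so passing
power/FWER checks here speaks to the multiple-testing machinery, not to
any particular real dataset.

**Counts design** (`simulate_counts_design`): two groups (sizes Binomial(n, ½),
redrawn until both ≥ 2), negative-binomial counts with variance
`μ + μ²/d`, `d = 10`; randomized gene assignment to the 6-term topology
with sharing across j leaf sets at probability ∝ 2^{−j}; fold changes
`2^β`, `β ~ Poisson(λ)`, in randomly chosen leaf sets; truth is any term
containing a fold-changed gene.  Per-gene control means come from a
log-normal sampler (log-mean 3.0, log-sd 1.5; median ≈ 20 counts) — a
documented stand-in for an empirical RNA-seq mean distribution, which is
why only qualitative patterns of this design (error control, power
ordering) are meaningful, never absolute power values.

`power_harness` drives either design from one seed through spawned
per-replicate streams, so results are reproducible and independent of
evaluation order.  The FWER estimate counts replicates rejecting at
least one term that is truly null *in that replicate*.

## Numerical choices

| constant | value | where | why |
|---|---|---|---|
| p/α comparison slack | 1e-12 | sequential & oracle tests | float-boundary ties |
| threshold floor | 1e-15 | same | α_i = 0 means untestable |
| regularity tolerance | 1e-12 | `validate_regularity` | sum checks |
| bisection tolerance | 1e-6 | adjusted p-values | ~20 iterations |
| p-value clipping | 1e-15 | combiners | finite quantiles |
| minimal-set enumeration cap | 15 candidates | `minimal_generating_subset` | exact below, greedy above |
| closure generator cap | 20 | closure enumeration | oracle-scale only |
| weight-update denominator ≤ 0 | weight set to 0 | `reject_update` | degenerate cycle convention |

Default `α = 0.05`; default focus level = DAG roots (full top-down);
default minimum set size 5 genes in the file-based pipeline.

## Known limitations

* Each bisection step re-runs the cascade, and each cascade round copies
  the graph for the virtual removal: fine into the hundreds of terms,
  not tuned for a 5,000-term ontology run with full adjusted p-values
  (rejection flags alone are much cheaper via `adjusted=False`).
* Automatic focus-level selection by atom count is a stub
  (`suggest_focus_level` raises); choose the roots or an a-priori level.
* Only is_a-style parent/child ontology edges are modeled; `part_of` and
  other relationship types are ignored by the OBO reader.
* The asymptotic global test assumes an (approximately) Gaussian
  phenotype; use the permutation method for small two-group designs.
* Degenerate families with content-identical terms are rejected at DAG
  construction (`infer_hasse`) or may make the minimal generating subset
  non-unique; the guarantees are stated for generic-position systems.
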