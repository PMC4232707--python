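"""Monte-Carlo power of the full top-down procedure on the 14-term design.

Each replicate draws a Gaussian phenotype Y and a 20x100 expression
matrix with signal r*Y added to the genes of three designated terms,
tests every term with the global score test, and adjusts with the Short
Focus Level at the root focus.  100 replicates keep this quick; the
acceptance script runs 1,000.
"""

import shortfocus as sf
from shortfocus.settests import global_test
from shortfocus.simulate import GaussianDesignConfig, simulate_gaussian_design

cfg = GaussianDesignConfig(n=20, r=0.5)
table, fwer, fwer_se = sf.power_harness(
    lambda rng: simulate_gaussian_design(cfg, rng),
    lambda study, genes, rng: global_test(study, genes),
    lambda dag, p, a: sf.sfl(dag, None, p, alpha=a, adjusted=False).rejected,
    n_reps=100,
    alpha=0.05,
    seed=7,
)
print(table.to_string(index=False))
print(f"\nFWER over true-null terms: {fwer:.3f} (MC-SE {fwer_se:.3f})")
print(
    "\n'truth' flags terms genuinely associated with Y (signal terms and "
    "their\nancestors); 'power' is the per-term rejection rate at FWER 0.05. "
    "Null terms\n(GO:05, 08, 09, 12, 14) should be rejected rarely."
)
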