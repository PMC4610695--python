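"""Why transform: power under skewed phenotypes.

Compares the plain score test with the rank-inverse-normal and
ordinal-residual transforms on cohorts whose phenotype noise is strongly
right-skewed (standardized Gamma(1,2)).  Each method sees the same
simulated datasets, so the comparison is paired.
"""

from atemp import SimulationScenario, run_methods_cell

scenario = SimulationScenario(
    kind="highdim", n=1000, n_phenotypes=5, maf=0.3,
    error_dist="gamma12", h2=0.006,  # variant explains 0.6% of variance
)

for cell in run_methods_cell(scenario, ["multiphen", "atemp-rn", "atemp-or"],
                             reps=500, alpha=5e-4, seed=11):
    print(f"{cell.method:10s} power = {cell.rejection_rate:.3f} "
          f"(+/- {cell.mc_se:.3f})")

# The rank-based transforms reject clearly more often than the plain test:
# with heavy-tailed or skewed phenotypes the identity kernel is inefficient
# and ranks recover the lost power.  Under normal phenotypes the plain test
# and atemp-rn perform alike (try error_dist="normal", h2=0.003).
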