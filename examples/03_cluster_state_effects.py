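"""Find eigenvector clusters whose eigenvalues shift across states.

Pools the fitted eigenmodes of all four states, repeats k-means over the
eigenvector-magnitude features with Hungarian centroid matching, and tests
per cluster whether eigenvalue stability or frequency differs across
states (ANOVA + Benjamini-Hochberg FDR).  The planted deep-state
stabilisation should light up exactly one cluster's stability rates.
"""

from neuromodes.experiments import modular_state_modes
from neuromodes import repeated_cluster_anova

modes_by_state, shifted_block = modular_state_modes(seed=0, stability_shift=0.15)
report = repeated_cluster_anova(modes_by_state, k_values=[5], n_iterations=200, seed=1)

cols = ["cluster", "measure", "significance_rate", "mean_cohens_f", "ref_corr_mean"]
print(report.summary[cols].to_string(index=False))
print(
    "\nsignificance_rate = % of the 200 clustering repetitions in which the\n"
    "cluster's state ANOVA stayed significant after FDR.  One cluster's\n"
    f"stability rate is ~100% (the block carrying the planted deep-state\n"
    f"damping increase, block {shifted_block}); every frequency rate stays at the null,\n"
    "because only eigenvalue magnitudes were shifted."
)
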