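"""Population time-series comparison between two genotype cohorts.

Two cohorts of 10 phantom animals each are run through the full pipeline
(render -> segment -> measure): a control cohort atrophying from 90 to
30 um over 0-50 h AHE, and a suppressed-atrophy cohort identical to
control until 30 h AHE and recovering afterwards.  Per 5-hour grid point
the fiber-diameter populations are compared with the two-sided
Mann-Whitney U test; the figure shows medians with 25-75% bands and
-log10(p) against the 0.01 threshold.
"""

import numpy as np

from flymuscle import aggregate_population, atrophy_cohort_features, compare_genotypes, plot_comparison

grid = np.arange(0.0, 61.0, 5.0)
features = atrophy_cohort_features(["control", "suppressed"], n_animals=10, grid_h=grid, seed=11)

result = compare_genotypes(features, "control", "suppressed", "avg_diameter_um", grid)
series = tuple(
    aggregate_population(features, "avg_diameter_um", grid, genotype=g)
    for g in ("control", "suppressed")
)

print(" t (h AHE)   control med   suppressed med   -log10(p)")
for t, mc, ms, nl in zip(grid, series[0].median, series[1].median, result.neg_log10_p):
    flag = "  *" if nl > 2 else ""
    print(f"  {t:6.1f}      {mc:8.1f}       {ms:8.1f}       {nl:7.2f}{flag}")

plot_comparison(result, series, "genotype_comparison.png")
print("\nwrote genotype_comparison.png")
# Points above -log10(p) = 2 (i.e. p < 0.01, marked *) appear only after
# the programmed 30-h divergence, mirroring a suppressed-atrophy phenotype.
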