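"""Differential accessibility on a directly simulated count matrix.

Simulates 1,000 consensus regions for 3 alpha vs 3 beta replicates with a
planted 4-fold (log2FC = 2) enrichment in 20% of regions, normalizes with
TMM, and runs the two-sided exact negative-binomial test. The printed
sensitivity is the fraction of planted regions called at p <= 0.05.
"""

import numpy as np

from isletkit.differential import nb_exact_test, tmm_factors
from isletkit.simulate import simulate_count_matrix

cm, truth = simulate_count_matrix(
    n_regions=1_000, group_sizes={"alpha": 3, "beta": 3},
    mean_count=100.0, dispersion=0.05, log2fc=2.0, frac_differential=0.20, seed=1,
)
cm.norm_factors = tmm_factors(cm)
peaks = nb_exact_test(cm, "alpha", "beta", alpha=0.05)

sig = np.array([p.significant for p in peaks])
planted = truth["differential"].to_numpy()
labels = np.array([p.enriched_in or "" for p in peaks])

print(f"TMM factors:        {np.round(cm.norm_factors, 4)}")
print(f"significant:        {sig.sum()} / {len(peaks)} regions at p <= 0.05")
print(f"sensitivity:        {sig[planted].mean():.3f} on {planted.sum()} planted regions")
print(f"false positives:    {sig[~planted].mean():.3f} of null regions (expect ~0.05)")
ok = (labels[planted & sig] == truth['enriched_in'].to_numpy()[planted & sig]).mean()
print(f"direction accuracy: {ok:.3f} among significant planted regions")
# A calibrated test keeps the null fraction near the 0.05 level while
# recovering essentially all planted 4-fold regions with the right label.
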