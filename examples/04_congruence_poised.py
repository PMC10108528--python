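"""Link TSS chromatin enrichment to expression; test for poised genes.

Feeds the classifier the planted promoter-peak enrichment and the emitted
RPKM table, reproducing the congruent / incongruent / unexpressed split,
then tests alpha-repressed genes for the stepwise poised pattern
(alpha < alpha-transdifferentiated < beta).
"""

from pathlib import Path

import pandas as pd

from isletkit.congruence import associate_tss_peaks, classify_congruence, poised_stepwise_test
from isletkit.differential import DifferentialPeak
from isletkit.intervals import GenomicInterval
from isletkit.simulate import SyntheticConfig, generate_world

world = generate_world(SyntheticConfig(seed=1), Path("scratch/example_world"))
expr = pd.read_csv(world.paths["expression"], sep="\t", index_col=0)
de = pd.read_csv(world.paths["expression_de"], sep="\t", index_col=0)

diff_peaks = [
    DifferentialPeak(
        region=GenomicInterval(p["chrom"], p["start"], p["end"]),
        log2fc=p["log2fc"] if p["enriched_in"] == "alpha" else -p["log2fc"],
        p_value=0.001, q_value=0.001, enriched_in=p["enriched_in"], significant=True,
    )
    for p in world.truth.differential_regions()
    if p["placement"] == "promoter" and p["enriched_in"] in ("alpha", "beta")
]
assoc, _ = associate_tss_peaks(diff_peaks, world.genes, window=3_000)
calls, summary, _ = classify_congruence(assoc, expr, ("alpha", "beta"), de=de)
print("congruence split (% of TSS-enriched genes):")
print(summary.round(2).to_string())

repressed = [c.gene for c in calls if c.klass == "incongruent_repressed_in_a"]
poised_calls, fractions = poised_stepwise_test(repressed, expr, origin_cell="alpha")
print(f"\nalpha-repressed genes: {len(repressed)}")
print(f"poised (stepwise alpha < transdiff < beta): {fractions['poised_beta_gene']:.1%}")
print(f"transition (transdiff maximal):             {fractions['transition_gene']:.1%}")
# A poised gene keeps its chromatin open in alpha cells while expression
# only rises through the alpha-to-beta transdifferentiated state.
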