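"""Generate the default synthetic islet world and inspect its truth manifest.

The world emulates a three-cell-type (alpha/beta/delta) ATAC study: 200
non-overlapping genes on two 3 Mb chromosomes, a 2,000-region peak universe
with 12.5% planted differential regions, replicate fragment files, an RPKM
expression table with planted congruent/repressed/unexpressed gene classes,
histone + TF ChIP tracks realizing planted enhancers, and motif-planted
sequences. Everything planted is recorded in truth.json.
"""

from collections import Counter
from pathlib import Path

from isletkit.simulate import SyntheticConfig, generate_world

world = generate_world(SyntheticConfig(seed=1), Path("scratch/example_world"))

print(f"genes placed:          {len(world.genes)}")
print(f"peak universe:         {len(world.truth.peaks)} regions")
print(f"  by placement:        {dict(Counter(p['placement'] for p in world.truth.peaks))}")
print(f"planted differential:  {len(world.truth.differential_regions())} regions")
print(f"gene classes:          {dict(Counter(world.truth.gene_classes.values()))}")
print(f"poised genes:          {len(world.truth.poised_genes)} "
      f"(of {len(world.truth.poised_genes) + len(world.truth.transition_genes)} alpha-repressed)")
print(f"planted enhancers:     {len(world.truth.enhancers)} "
      f"({sum(1 for e in world.truth.enhancers if e['state'] == 'active')} active)")
print(f"files under:           {world.outdir}")
# The placement counts are the ground truth the annotation stage must
# recover; the differential regions are what the NB exact test must find.
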