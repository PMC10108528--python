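"""Rule-based enhancer calling from histone co-localization and TF binding.

Runs the chain on the synthetic epigenome: H3K27ac AND H3K4me1 AND >= 1 TF
track gives putative enhancers; the ATAC filter keeps those open in at
least one cell type; the curated-catalog filter gives the conservative
list. A permutation test quantifies co-localization against chance.
"""

from pathlib import Path

from isletkit.enhancers import (
    call_putative,
    filter_accessible,
    filter_catalog,
    permutation_enrichment,
    specificity_partition,
)
from isletkit.differential import build_consensus
from isletkit.intervals import RegionSet, read_regions
from isletkit.simulate import SyntheticConfig, generate_world

world = generate_world(SyntheticConfig(seed=1), Path("scratch/example_world"))
h27 = read_regions(world.paths["histone"]["H3K27ac"])
h1 = read_regions(world.paths["histone"]["H3K4me1"])
tf_tracks = {name: read_regions(p) for name, p in world.paths["tf"].items()}

putative = call_putative(h27, h1, tf_tracks)
print(f"putative enhancers (histones + TF): {len(putative)}")
print(f"  co-binding counts range {putative[-1].cobinding_count}..{putative[0].cobinding_count}")

atac_by_cell = {
    cell: build_consensus(
        [read_regions(p, format="narrowpeak", meta={"cell_type": c, "replicate": r})
         for (c, r), p in world.paths["atac"].items() if c == cell],
        min_replicates=2,
    )
    for cell in world.cfg.cell_types
}
_, active = filter_accessible(putative, atac_by_cell)
print(f"active (open in >= 1 cell type):    {len(active)}")

catalog = read_regions(world.paths["catalog"])
conservative = filter_catalog(active, catalog)
print(f"conservative (catalog-supported):   {len(conservative)}")
print("\naccessibility specificity of active calls:")
print(specificity_partition(active).round(2).to_string())

res = permutation_enrichment(
    RegionSet([c.region for c in active]), h27, world.cfg.chrom_sizes, n_perm=99, seed=13
)
print(f"\npermutation: observed overlap {res.observed_overlap}, null mean {res.null_mean:.2f}, "
      f"z = {res.z:.1f}, empirical p = {res.p_empirical:.4f}")
# The planted chain is recovered exactly (no decoys survive the conjunction)
# and the co-localization p-value attains its minimum 1/(n_perm + 1).
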