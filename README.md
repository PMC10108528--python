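# isletkit

Chromatin-accessibility integration for pancreatic islet cell types.

Glucagon-secreting alpha cells, insulin-secreting beta cells, and
somatostatin-secreting delta cells share a progenitor but maintain distinct
identities, and the chromatin accessibility landscape around their genes is
a key layer of that identity. `isletkit` reimplements, as a tested and
reusable library, the analysis chain that links bulk ATAC-seq peak calls
from FACS-purified alpha/beta/delta cells to regulatory interpretation:

- **Differential accessibility** — consensus peaks across replicates
  (supported by ≥ 2 replicates of a cell type), fragment counting by the
  midpoint rule, TMM normalization, and a two-sided exact negative-binomial
  test per region. A region is differentially enriched at *p* ≤ 0.05; the
  common dispersion φ is estimated by method of moments and counts are
  scaled to a common effective library before conditioning on the pairwise
  total.
- **Genome annotation** — each peak is assigned one category by midpoint
  precedence (promoter-proximal ≻ exon ≻ first intron ≻ other intron ≻
  downstream ≻ distal-intergenic), with the symmetric TSS ± 3 kb promoter
  window, genome-background percentages, TSS density profiles, and FRiP QC
  against the 0.3 benchmark.
- **Congruence & poised genes** — genes whose TSS carries a significantly
  enriched peak are classified *congruent* (expression follows chromatin),
  *incongruent/repressed* (open chromatin, low expression), or
  *unexpressed*; repressed genes are tested for the stepwise poised pattern
  `origin < transdifferentiated < beta` using transcriptomes of beta cells
  with an alpha or delta lineage history.
- **Motif scanning** — PWMs (JASPAR `.pfm` / HOCOMOCO `.pcm`) scored on
  both strands with exact p-values from a dynamic program over a
  discretized log-odds lattice; per-category Fisher-exact preference tests
  restricted to expressed TFs (RPKM > 0); validation of genome-mapped hits
  against ChIP peaks as true/false-positive percentages.
- **Enhancer calling** — the rule-based chain: base-level co-localization
  of H3K27ac and H3K4me1 with ≥ 1 TF ChIP track gives putative enhancers
  (with per-region co-binding counts); filtering against open chromatin
  gives active enhancers with a per-cell accessibility partition
  (common / pairwise / cell-unique); a curated catalog filter gives the
  conservative list. Poised (H3K4me1 only) and active-promoter (H3K4me3)
  states are distinguished, and co-localization is tested against chance by
  length-preserving permutation.
- **Synthetic data with ground truth** — a first-class generator plants a
  complete "islet world" (genes, replicate peak/fragment files, expression
  with congruent/repressed/poised classes, histone/TF/catalog tracks with
  decoys, motif-planted sequences) and records every planted structure in
  a machine-readable truth manifest, so each stage can be checked for exact
  recovery.

## Worked example

Run the whole chain on the default synthetic world (about ten seconds):

```python
from pathlib import Path
from isletkit import PipelineConfig, SyntheticConfig, run_all

results = run_all(PipelineConfig(outdir=Path("out"), synthetic=SyntheticConfig(seed=1), seed=1))
print(results["report"]["enhancers"])
```

prints

```
{'n_putative': 64, 'n_active': 58, 'n_conservative': 29,
 'specificity_pct': {'common_all': 34.48, 'pair_ab': 10.34, 'pair_ad': 10.34,
 'pair_bd': 10.34, 'unique_alpha': 8.62, 'unique_beta': 17.24,
 'unique_delta': 8.62, 'inaccessible': 0.0},
 'permutation': {'observed': 58, 'null_mean': 0.86, 'z': 65.2, 'p_empirical': 0.009901}}
```

— the 64 putative calls are exactly the planted active enhancers (zero
decoys survive the histone + TF conjunction), 58 remain after the
open-chromatin filter, 29 after the catalog filter, and the permutation
test attains its minimum empirical p of 1/(99 + 1). The same run reports
a ~17.9% differential fraction for alpha vs beta (250 planted 4-fold
regions plus the ~5% null rate), a 50 / 36 / 14 congruent / incongruent /
unexpressed split among TSS-enriched genes, and an 80% poised fraction
among alpha-repressed genes. The `examples/` directory walks through each
capability separately with commentary; each script prints the numbers it
computes.

The same pipeline runs from a shell:

```bash
isletkit --outdir out --seed 1 all
isletkit --outdir out --seed 1 enhancers   # one stage's report section
```

or on user-supplied tracks via a JSON config (`isletkit --config cfg.json all`)
pointing at narrowPeak/BED/GTF/TSV inputs.

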