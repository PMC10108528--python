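# Methods

`isletkit` analyses chromatin accessibility of pancreatic alpha, beta, and
delta cells and integrates it with expression, motif, and ChIP evidence.
This note documents the statistical procedures, the defaults and why they
were chosen, what the synthetic world does and does not emulate, and the
numerical choices that affect results.

## Coordinates and interval algebra

All coordinates are 0-based half-open (BED convention) internally; GTF
input is converted on read (1-based inclusive → half-open). Region sets are
canonical — sorted by (chrom, start, end) with exact duplicate records
collapsed — so membership questions have set semantics. Overlap means ≥ 1
shared base unless a caller raises `min_overlap_bp`; overlap filters return
whole input intervals (membership), while enhancer candidate construction
uses clipped base-level intersection geometry (co-localization is a
property of bases, not of either track's peak boundaries). Merging joins
intervals whose gap is ≤ `max_gap` (default 0, so touching intervals merge,
as interval tooling conventionally does; a 1 bp gap does not). Fragment
files are counted with multiplicity through a fast table reader; they are
the one input deliberately exempt from duplicate collapsing.

## Consensus, counting, and the exact NB test

A consensus region is a merged union interval supported by peaks from at
least `min_replicates` (default 2) distinct replicates of one cell type
(a global pooling mode is available). Fragments are assigned to regions by
their midpoint, so each fragment counts exactly once even across adjacent
regions.

Between-sample composition is corrected by TMM: M and A values against the
highest-depth reference sample, double trimming (30% on M, 5% on A),
weights from the delta-method variance, and factors rescaled to geometric
mean 1.

The pairwise test scales counts to the geometric mean of the effective
library sizes, estimates a single common dispersion φ by method of moments
on within-group means and variances (floored at 1e-6), and computes a
two-sided exact p-value by conditioning the two group sums on their total:
each sum is negative binomial with per-sample mean t/(n_a + n_b) and size
n_group/φ, the conditional distribution over the rounded total is
normalized explicitly, and p = 2 × min(lower tail, upper tail), capped at
1. Group sums are rounded individually before forming the total so the
test is exactly symmetric under swapping the groups. Log2 fold changes use
normalized group means with a prior count of 0.5 (no infinite ratios at
zero counts). Significance is the unadjusted p ≤ 0.05; a Benjamini–
Hochberg q-value column is emitted for reference but does not drive the
flag. This is a deliberate simplification of the edgeR family of tests:
no tagwise empirical-Bayes shrinkage and no quantile adjustment, trading
exactness of that machinery for a fully specified, deterministic test that
is calibrated at desk scale (null type-I error within [0.03, 0.07] and KS
distance from uniform < 0.05 in the acceptance suite).

## Genome annotation

The feature index derives, per gene: a symmetric promoter window
TSS ± `promoter_window` (default 3,000 bp; an upstream-only asymmetric
mode is available behind a flag — both windows appear in common annotation
practice and the symmetric form matches TSS-centered density profiles),
exons, introns as inter-exon gaps with the TSS-adjacent gap labeled
"first", and a strand-aware downstream window (3 kb past the 3' end,
mirroring the promoter width; UTRs are not separate categories — UTR bases
count as exonic). Classification is a function: the peak midpoint is looked
up in the features under the fixed precedence promoter ≻ exon ≻ first
intron ≻ other intron ≻ downstream ≻ distal; a peak whose midpoint hits no
feature but which overlaps one falls back to any-overlap under the same
precedence. Genome-background percentages partition every base of the
genome by the same precedence, so both peak and background columns sum to
100. FRiP is the fraction of fragment midpoints inside the merged peak set,
with a pass flag at the conventional 0.3 benchmark.

## Congruence and poised genes

A gene enters the congruence analysis when a significant differential peak
has its midpoint within the TSS window (default 3 kb); with several such
peaks the smallest p-value is representative and all are kept in an audit
list. Classification against the two compared cell types: *unexpressed*
when both RPKM values are at or below the floor (default 0 — "expressed"
is RPKM > 0); *congruent* when the peak-enriched cell is also the
significantly-higher-expression cell (companion expression test with
defaults |log2FC| > 1 and BH q ≤ 0.05 when supplied; raw RPKM ordering
otherwise); else *incongruent*, with the lower-expression cell labeled
repressed (ties resolve to the peak-enriched cell, which keeps labels
invariant under swapping the comparison).

Repressed genes are then read out through transdifferentiated-beta
transcriptomes: *poised* requires the strict stepwise ordering
origin < transdifferentiated < beta; *transition* requires the
transdifferentiated value to be the strict maximum; anything else,
including ties, is *other* — strictness is the only reading under which
"intermediate" is well defined.

## Motif scanning

Count matrices are normalized per column with a pseudocount (default 0.8)
split by the background (uniform by default), and scored as log2 odds. The
null score distribution of a background L-mer is computed exactly by
dynamic programming over a lattice of 0.005-bit bins (per-column rounding,
then convolution); the p-value of a score is the lattice upper tail, and
the scan threshold for a target p (default 1e-4, a common scan default) is
the smallest lattice score whose tail is at or below it. Both strands are
scanned (minus strand via the reverse-complement matrix on the forward
sequence); `N` bases score 0 (background). The per-column rounding places
any word within L/2 bins of its true score, which is the stated tolerance
against exhaustive enumeration. The attainable maximum score maps to the
top lattice cell, so the consensus word always has a positive p-value.

Regional preference replaces deviation-score machinery with a defined
categorical test: for each motif, cell, and genome category, a 2×2 Fisher
exact test of motif presence in "peaks of that category enriched in that
cell" versus all other consensus peaks, BH-corrected across the grid, with
a presence flag at q ≤ 0.05 and odds ratio > 1. Motifs are only evaluated
in cells where their TF is expressed (RPKM > 0), through an explicit
motif-to-gene mapping table (no fuzzy name matching). ChIP validation
reports all three rates explicitly — % of ChIP peaks with ≥ 1 hit (true
positives), its complement (false negatives), and % of universe regions
bearing hits but no ChIP overlap (false positives) — optionally with the
ChIP set first restricted to the open-chromatin universe.

## Enhancer calling

Candidates are the base-level intersection intervals of the merged H3K27ac
and H3K4me1 tracks; a candidate is emitted iff at least one TF ChIP track
overlaps it. The co-binding count is the number of distinct TF tracks
overlapping (default), with a per-peak variant (every overlapping ChIP
interval) behind a flag — the field's "sites of co-binding" phrasing
supports both readings. H3K4me3 takes precedence as a promoter mark:
regions overlapping it are active promoters and are excluded from enhancer
lists; both activating marks give *active*, H3K4me1 alone gives *poised*.
The ATAC filter annotates per-cell accessibility and keeps calls open in
≥ 1 cell type; the accessibility set determines one of seven specificity
classes (all three cells, three pairs, three unique) with percentages over
accessible calls; the catalog filter keeps calls overlapping the curated
enhancer track, and the chain is a strict subset sequence
conservative ⊆ active ⊆ putative.

Permutation enrichment re-places each query region uniformly on its own
chromosome (lengths preserved, overlaps between placed regions not
prevented — the standard randomize-regions scheme; masking is out of
scope), recounts overlaps with the target track, and reports
p = (1 + #{null ≥ observed})/(n_perm + 1) with a z-score against the null
mean and SD; 100 permutations by default, matching common practice.

## The synthetic world

The generator's defaults define the study conditions: 3 cell types × 3
replicates; two 3 Mb chromosomes (sized so that 200 genes with 3 kb flanks
leave room for 1,400 distal peaks; the gene bodies span 9.6 kb with four
300 bp exons so that two introns per gene lie wholly outside the promoter
window); a 2,000-region peak universe (200 promoter, 400 deep-intronic,
1,400 distal); 12.5% differential regions at a planted log2FC of 2 —
within the ~10–15% per-comparison range such studies report — with NB
fragment counts (mean 60, dispersion 0.05) and per-replicate peak
observation probability 0.97, so the ≥ 2-replicate consensus recovers
essentially the whole universe; background fragments bring FRiP to ~0.63,
comfortably above the 0.3 benchmark.

Gene classes are assigned by deterministic partition — 50% congruent
(split evenly between the two cells), 36% repressed (5:1 toward
alpha-repressed, preserving the strong asymmetry such comparisons show),
14% unexpressed — with noise only in count and (optional) RPKM magnitudes.
That makes classifier acceptance exact rather than statistical: the
classifier fed the planted TSS enrichment and the emitted expression table
must reproduce the manifest for 100% of genes. The poised fraction is 0.8
of alpha-repressed genes, a round value chosen so the deterministic
partition is integral (0.8 × 60 = 48) and recovery can be asserted
exactly. Planted enhancers (64 active across eight specificity classes,
plus poised, active-promoter, and four decoy kinds with incomplete mark
combinations) sit on a distal grid disjoint from genes and ATAC peaks;
co-binding counts cycle 1..8 across the available TF tracks; half of the
accessible enhancers carry catalog support. Motif sequences are i.i.d.
uniform ACGT with exact-consensus plants at recorded offsets and strands.

What the world does **not** emulate: read-level artifacts (duplicates,
mitochondrial contamination, mappability), overdispersed peak-width and
signal distributions, correlated replicate structure, sex or pooling
covariates, genes overlapping one another or their neighbors' regulatory
windows, GC-biased motif backgrounds, and real marks' partial overlaps.
Passing recovery tests therefore demonstrates the correctness of the
implemented rules and the calibration of the tests on clean NB data, not
performance on real sequencing data.

## Determinism and numerical choices

Every random stage derives from explicit integer seeds (sub-streams per
generator stage), and all file emissions use fixed formats, so identical
config and seeds give byte-identical outputs; the run manifest of SHA-256
checksums is the determinism witness. Scores are written with 6
significant digits (round-trip identity holds at that precision);
dispersion is floored at 1e-6; the score lattice is 0.005 bits; empirical
permutation p-values are bounded below by 1/(n_perm + 1) by construction.

## Limitations

The exact test uses one common dispersion; strongly tagwise-variable real
data would be moderated differently. Nearest-gene assignment is by nearest
TSS (no regulatory-domain model), one canonical transcript per gene.
bigWig signal, blacklists, peak re-centering, pathway enrichment, and
chromatin-interaction integration are out of scope. The acceptance
experiments run at desk scale (thousands of regions, two small
chromosomes) — sizes chosen so the full suite completes in minutes while
leaving each statistical check enough resolution to be meaningful.
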