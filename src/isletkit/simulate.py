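"""Synthetic islet-world generator with a machine-readable truth manifest.

The generator emulates the statistical structure of a three-cell-type
(alpha/beta/delta) chromatin-accessibility study: replicate ATAC peak calls
over a shared peak universe, negative-binomial fragment counts with a
planted log2 fold change in a known fraction of regions, promoter /
intronic / distal peak placement on non-overlapping gene models, an RPKM
expression table realizing congruent / repressed / unexpressed gene classes
(with a stepwise poised subset read out through transdifferentiated-beta
transcriptomes), histone + TF ChIP tracks realizing active/poised enhancer
definitions with known co-binding counts, a curated-catalog track, and
motif-planted sequences.

Everything planted is recorded in a :class:`TruthManifest`, and all outputs
are byte-identical across runs with the same seed and config. Gene classes
and enhancer specificity classes are assigned by deterministic partition
(not sampling), so classifier recovery can be checked exactly; randomness
enters only through placements and count/fragment magnitudes.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .differential import CountMatrix
from .genes import Gene, tss_regions, write_gtf
from .intervals import GenomicInterval, RegionSet, write_regions

# fixed sub-stream labels so stages are reproducible independently of call order
_RNG_ANNOTATION = 1
_RNG_ACCESSIBILITY = 2
_RNG_EXPRESSION = 3
_RNG_EPIGENOME = 4
_RNG_MOTIFS = 5
_RNG_PLAN = 6

GENE_CLASSES = (
    "congruent_in_alpha",
    "congruent_in_beta",
    "repressed_in_alpha",
    "repressed_in_beta",
    "unexpressed",
)


@dataclass(frozen=True)
class MotifSpec:
    motif_id: str
    tf_name: str
    consensus: str
    plant_rate: float


DEFAULT_MOTIFS = (
    MotifSpec("M_PDX1", "Pdx1", "GTCTAATGAC", 0.15),
    MotifSpec("M_NEUROD1", "Neurod1", "ACCATCTGTT", 0.15),
    MotifSpec("M_MAFA", "Mafa", "TGCTGACTCA", 0.15),
    MotifSpec("M_RFX6", "Rfx6", "GTTGCCATGG", 0.15),
)

DEFAULT_TF_NAMES = ("Pdx1", "Nkx6-1", "Neurod1", "Insm1", "Foxa2", "Nkx2-2", "Rfx6", "Mafa")


@dataclass
class SyntheticConfig:
    """Study conditions of the synthetic world (defaults emulate the desk-scale design)."""

    chrom_sizes: dict[str, int] = field(default_factory=lambda: {"chr1": 3_000_000, "chr2": 3_000_000})
    n_genes: int = 200
    cell_types: tuple[str, ...] = ("alpha", "beta", "delta")
    replicates_per_cell: int = 3
    n_consensus_peaks: int = 2000
    frac_differential: float = 0.125
    planted_log2fc: float = 2.0
    nb_dispersion: float = 0.05
    mean_count: float = 60.0
    peak_width: int = 250
    fragment_length: int = 100
    observation_prob: float = 0.97
    frip_target: float = 0.6
    congruence_plan: dict[str, float] = field(
        default_factory=lambda: {"congruent": 0.50, "incongruent_repressed": 0.36, "unexpressed": 0.14}
    )
    repressed_in_b_share: float = 1.0 / 6.0
    poised_fraction: float = 0.8
    n_enhancers: dict[str, int] = field(
        default_factory=lambda: {
            "common_all": 20,
            "unique_alpha": 5,
            "unique_beta": 10,
            "unique_delta": 5,
            "pair_ab": 6,
            "pair_ad": 6,
            "pair_bd": 6,
            "inaccessible": 6,
        }
    )
    n_poised_enhancers: int = 10
    n_active_promoter_regions: int = 8
    n_decoy_regions: int = 20
    tf_names: tuple[str, ...] = DEFAULT_TF_NAMES
    enhancer_width: int = 600
    catalog_support: float = 0.5
    n_catalog_extra: int = 30
    motif_set: tuple[MotifSpec, ...] = DEFAULT_MOTIFS
    n_motif_sequences: int = 120
    motif_sequence_length: int = 200
    expression_noise_sd: float = 0.0
    seed: int = 0

    # gene geometry: 4 exons of 300 bp, 3 introns of 2,800 bp (span 9,600 bp),
    # long enough that two introns lie wholly outside the 3 kb promoter window
    exon_width: int = 300
    intron_width: int = 2800
    n_exons: int = 4

    def __post_init__(self) -> None:
        for name, frac in (
            ("frac_differential", self.frac_differential),
            ("observation_prob", self.observation_prob),
            ("poised_fraction", self.poised_fraction),
            ("catalog_support", self.catalog_support),
            ("frip_target", self.frip_target),
        ):
            if not 0.0 <= frac <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {frac}")
        if abs(sum(self.congruence_plan.values()) - 1.0) > 1e-9:
            raise ValueError("congruence_plan proportions must sum to 1")
        for c, L in self.chrom_sizes.items():
            if L < 10_000:
                raise ValueError(f"chromosome {c} too short ({L} bp); need >= 10,000")
        if self.planted_log2fc <= 0 or self.nb_dispersion <= 0 or self.mean_count <= 0:
            raise ValueError("planted_log2fc, nb_dispersion and mean_count must be positive")
        max_k = max(self.n_enhancers.values(), default=0)
        if max_k and len(self.tf_names) < 1:
            raise ValueError("at least one TF track is required")

    @property
    def gene_span(self) -> int:
        return self.n_exons * self.exon_width + (self.n_exons - 1) * self.intron_width

    @property
    def samples(self) -> list[tuple[str, str]]:
        return [(c, f"r{i + 1}") for c in self.cell_types for i in range(self.replicates_per_cell)]


@dataclass
class TruthManifest:
    """Ground truth for every planted structure, verifiable from the emitted files."""

    peaks: list[dict] = field(default_factory=list)          # universe regions + placement + differential info
    gene_classes: dict[str, str] = field(default_factory=dict)
    gene_enriched_cell: dict[str, str] = field(default_factory=dict)
    poised_genes: list[str] = field(default_factory=list)
    transition_genes: list[str] = field(default_factory=list)
    enhancers: list[dict] = field(default_factory=list)      # planted enhancer regions + class/state/cobinding
    decoys: list[dict] = field(default_factory=list)
    motif_plants: dict[str, dict] = field(default_factory=dict)

    def differential_regions(self) -> list[dict]:
        return [p for p in self.peaks if p["differential"]]

    def to_json(self, path: str | Path) -> Path:
        path = Path(path)
        path.write_text(json.dumps(dataclasses.asdict(self), indent=2, sort_keys=True))
        return path

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthManifest":
        return cls(**json.loads(Path(path).read_text()))


@dataclass
class World:
    """All file paths and in-memory objects of one generated synthetic world."""

    cfg: SyntheticConfig
    outdir: Path
    genes: list[Gene]
    truth: TruthManifest
    paths: dict


# ---------------------------------------------------------------------------
# gene class partition (deterministic; no randomness)
# ---------------------------------------------------------------------------

def partition_gene_classes(cfg: SyntheticConfig, gene_ids: list[str]) -> tuple[dict[str, str], list[str], list[str]]:
    """Assign congruence classes by deterministic partition of the gene list.

    Counts are exact (rounded once, remainder absorbed by the unexpressed
    class); the poised subset is the leading fraction of alpha-repressed
    genes. Returns (class map, poised genes, transition genes).
    """
    n = len(gene_ids)
    n_cong = int(round(cfg.congruence_plan["congruent"] * n))
    n_rep = int(round(cfg.congruence_plan["incongruent_repressed"] * n))
    n_rep_b = int(round(cfg.repressed_in_b_share * n_rep))
    n_rep_a = n_rep - n_rep_b
    classes: dict[str, str] = {}
    for i, gid in enumerate(gene_ids):
        if i < n_cong:
            classes[gid] = "congruent_in_alpha" if i % 2 == 0 else "congruent_in_beta"
        elif i < n_cong + n_rep_a:
            classes[gid] = "repressed_in_alpha"
        elif i < n_cong + n_rep:
            classes[gid] = "repressed_in_beta"
        else:
            classes[gid] = "unexpressed"
    rep_a = [g for g in gene_ids if classes[g] == "repressed_in_alpha"]
    n_poised = int(round(cfg.poised_fraction * len(rep_a)))
    return classes, rep_a[:n_poised], rep_a[n_poised:]


def _enriched_cell_for(gid: str, klass: str, index: int) -> str:
    if klass == "congruent_in_alpha":
        return "alpha"
    if klass == "congruent_in_beta":
        return "beta"
    if klass == "repressed_in_alpha":
        return "alpha"
    if klass == "repressed_in_beta":
        return "beta"
    return "alpha" if index % 2 == 0 else "beta"  # unexpressed: alternate


# ---------------------------------------------------------------------------
# annotation
# ---------------------------------------------------------------------------

def generate_annotation(cfg: SyntheticConfig, outdir: str | Path) -> tuple[list[Gene], Path, Path]:
    """Place non-overlapping multi-exon genes on both strands; emit GTF + TSS BED.

    Each chromosome is tiled into equal slots; one gene per slot, placed so
    that its promoter and downstream 3 kb windows stay inside the slot
    (hence genes and their flanking windows never overlap).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, _RNG_ANNOTATION])
    total = sum(cfg.chrom_sizes.values())
    genes: list[Gene] = []
    if cfg.n_genes > 0:
        # genes per chromosome proportional to length
        chroms = sorted(cfg.chrom_sizes)
        alloc = {c: int(round(cfg.n_genes * cfg.chrom_sizes[c] / total)) for c in chroms}
        drift = cfg.n_genes - sum(alloc.values())
        alloc[chroms[0]] += drift
        gidx = 0
        for chrom in chroms:
            n_here = alloc[chrom]
            if n_here == 0:
                continue
            slot = cfg.chrom_sizes[chrom] // n_here
            margin = 3000
            if slot < cfg.gene_span + 2 * margin + 200:
                raise ValueError(
                    f"genome too small to place {cfg.n_genes} non-overlapping genes "
                    f"with 3 kb flanks (slot {slot} bp < {cfg.gene_span + 2 * margin + 200} bp)"
                )
            for k in range(n_here):
                lo = k * slot + margin
                hi = (k + 1) * slot - cfg.gene_span - margin
                start = int(rng.integers(lo, hi + 1))
                strand = "+" if rng.random() < 0.5 else "-"
                exons = []
                pos = start
                for e in range(cfg.n_exons):
                    exons.append((pos, pos + cfg.exon_width))
                    pos += cfg.exon_width + cfg.intron_width
                gidx += 1
                genes.append(
                    Gene(
                        gene_id=f"g{gidx:04d}",
                        chrom=chrom,
                        start=start,
                        end=start + cfg.gene_span,
                        strand=strand,
                        exons=tuple(exons),
                    )
                )
    gtf = write_gtf(genes, outdir / "genes.gtf")
    tss_bed = write_regions(tss_regions(genes), outdir / "tss.bed", format="bed6")
    return genes, gtf, tss_bed


# ---------------------------------------------------------------------------
# distal grid (shared by distal ATAC peaks and enhancer-module regions)
# ---------------------------------------------------------------------------

def _distal_grid(cfg: SyntheticConfig, genes: list[Gene]) -> list[tuple[str, int]]:
    """Candidate distal slots (width enhancer_width + 50) outside gene +/- 3 kb."""
    slot_w = cfg.enhancer_width + 50
    margin = 3000
    forbidden: dict[str, list[tuple[int, int]]] = {c: [] for c in cfg.chrom_sizes}
    for g in genes:
        forbidden[g.chrom].append((g.start - margin, g.end + margin))
    slots: list[tuple[str, int]] = []
    for chrom in sorted(cfg.chrom_sizes):
        zones = sorted(forbidden[chrom])
        cursor = 0
        pieces: list[tuple[int, int]] = []
        for s, e in zones:
            if s > cursor:
                pieces.append((cursor, s))
            cursor = max(cursor, e)
        if cursor < cfg.chrom_sizes[chrom]:
            pieces.append((cursor, cfg.chrom_sizes[chrom]))
        for s, e in pieces:
            p = s
            while p + slot_w <= e:
                slots.append((chrom, p))
                p += slot_w
    return slots


# ---------------------------------------------------------------------------
# enhancer plan
# ---------------------------------------------------------------------------

_CLASS_TO_CELLS = {
    "common_all": ("alpha", "beta", "delta"),
    "pair_ab": ("alpha", "beta"),
    "pair_ad": ("alpha", "delta"),
    "pair_bd": ("beta", "delta"),
    "unique_alpha": ("alpha",),
    "unique_beta": ("beta",),
    "unique_delta": ("delta",),
    "inaccessible": (),
}

_DECOY_KINDS = ("h3k27ac_only", "h3k4me1_only", "histones_no_tf", "tf_only")


def plan_enhancers(cfg: SyntheticConfig, genes: list[Gene], truth: TruthManifest) -> list[tuple[str, int]]:
    """Reserve distal slots for enhancers/decoys/catalog and record the plan.

    Returns the remaining (unreserved) slots for distal ATAC peak placement.
    Co-binding counts cycle 1..n_tf across planted active enhancers; catalog
    support is assigned to every other accessible enhancer (exact counts).
    """
    for klass in cfg.n_enhancers:
        if klass not in _CLASS_TO_CELLS:
            raise ValueError(f"unknown enhancer specificity class {klass!r}")
    n_tf = len(cfg.tf_names)
    rng = np.random.default_rng([cfg.seed, _RNG_PLAN])
    slots = _distal_grid(cfg, genes)
    order = rng.permutation(len(slots))
    slots = [slots[i] for i in order]

    n_active = sum(cfg.n_enhancers.values())
    need = n_active + cfg.n_poised_enhancers + cfg.n_active_promoter_regions + cfg.n_decoy_regions + cfg.n_catalog_extra
    if len(slots) < need:
        raise ValueError(f"not enough distal space for {need} planted regions (have {len(slots)} slots)")

    take = iter(slots)
    w = cfg.enhancer_width
    i_active = 0
    n_accessible_seen = 0
    for klass in sorted(cfg.n_enhancers):
        for _ in range(cfg.n_enhancers[klass]):
            chrom, pos = next(take)
            k = (i_active % n_tf) + 1
            tfs = tuple(cfg.tf_names[(i_active + j) % n_tf] for j in range(k))
            cells = _CLASS_TO_CELLS[klass]
            catalog = False
            if cells:
                catalog = (n_accessible_seen % 2 == 0) if cfg.catalog_support > 0 else False
                # catalog_support of 0.5 -> every other accessible enhancer; other
                # rates fall back to the leading fraction
                n_accessible_seen += 1
            truth.enhancers.append(
                {
                    "chrom": chrom,
                    "start": pos + 25,
                    "end": pos + 25 + w,
                    "class": klass,
                    "cells": list(cells),
                    "state": "active",
                    "cobinding": k,
                    "tfs": list(tfs),
                    "catalog": catalog,
                }
            )
            i_active += 1
    for _ in range(cfg.n_poised_enhancers):
        chrom, pos = next(take)
        truth.enhancers.append(
            {
                "chrom": chrom, "start": pos + 25, "end": pos + 25 + w,
                "class": "inaccessible", "cells": [], "state": "poised",
                "cobinding": 0, "tfs": [], "catalog": False,
            }
        )
    for _ in range(cfg.n_active_promoter_regions):
        chrom, pos = next(take)
        truth.enhancers.append(
            {
                "chrom": chrom, "start": pos + 25, "end": pos + 25 + w,
                "class": "inaccessible", "cells": [], "state": "active_promoter",
                "cobinding": 0, "tfs": [], "catalog": False,
            }
        )
    for j in range(cfg.n_decoy_regions):
        chrom, pos = next(take)
        truth.decoys.append(
            {
                "chrom": chrom, "start": pos + 25, "end": pos + 25 + w,
                "kind": _DECOY_KINDS[j % len(_DECOY_KINDS)],
            }
        )
    for _ in range(cfg.n_catalog_extra):
        chrom, pos = next(take)
        truth.decoys.append(
            {"chrom": chrom, "start": pos + 25, "end": pos + 25 + w, "kind": "catalog_only"}
        )
    return list(take)


def _catalog_fraction_exact(cfg: SyntheticConfig, truth: TruthManifest) -> None:
    """Re-assign catalog flags as the leading catalog_support fraction when != 0.5."""
    accessible = [e for e in truth.enhancers if e["state"] == "active" and e["cells"]]
    if abs(cfg.catalog_support - 0.5) < 1e-12:
        return
    n_cat = int(round(cfg.catalog_support * len(accessible)))
    for i, e in enumerate(accessible):
        e["catalog"] = i < n_cat


# ---------------------------------------------------------------------------
# accessibility (peak universe, replicate narrowPeaks, fragment BEDs)
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    size = 1.0 / dispersion
    p = size / (size + np.asarray(mean, dtype=float))
    return rng.negative_binomial(size, p)


def generate_accessibility(
    cfg: SyntheticConfig,
    genes: list[Gene],
    truth: TruthManifest,
    outdir: str | Path,
    distal_slots: list[tuple[str, int]] | None = None,
) -> dict:
    """Emit per-sample narrowPeak + fragment BED files and record differential truth.

    The peak universe combines one promoter-proximal peak per gene, two
    deep-intronic peaks per gene, and distal-intergenic peaks; a fraction of
    regions is differential (mean x 2^planted_log2fc in exactly one cell).
    Planted enhancer regions additionally contribute cell-restricted peaks.
    Fragment counts are negative binomial; off-peak background fragments
    bring FRiP down to ~frip_target.
    """
    outdir = Path(outdir)
    (outdir / "atac").mkdir(parents=True, exist_ok=True)
    (outdir / "fragments").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, _RNG_ACCESSIBILITY])
    w = cfg.peak_width
    margin = 3000

    if distal_slots is None:
        distal_slots = _distal_grid(cfg, genes)
        order = rng.permutation(len(distal_slots))
        distal_slots = [distal_slots[i] for i in order]

    gene_ids = [g.gene_id for g in genes]
    if not truth.gene_classes:
        classes, poised, transition = partition_gene_classes(cfg, gene_ids)
        truth.gene_classes = classes
        truth.poised_genes = poised
        truth.transition_genes = transition

    universe: list[dict] = []
    # promoter peaks: one per gene, midpoint within +/- 1,800 bp of the TSS
    for g in genes:
        offset = int(rng.integers(-1800, 1801))
        mid = g.tss + offset
        universe.append(
            {
                "chrom": g.chrom, "start": mid - w // 2, "end": mid - w // 2 + w,
                "placement": "promoter", "gene": g.gene_id,
            }
        )
    # intronic peaks: the introns lying wholly > 3 kb from the TSS
    n_intron_target = 2 * len(genes)
    for g in genes:
        usable = [
            (s, e)
            for (s, e) in g.introns()
            if min(abs(s - g.tss), abs(e - 1 - g.tss)) >= margin + 200
            and abs(s - g.tss) >= margin + 200
            and abs(e - g.tss) >= margin + 200
        ]
        for (s, e) in usable[:2]:
            mid = int(rng.integers(s + w // 2 + 10, e - w // 2 - 10))
            universe.append(
                {"chrom": g.chrom, "start": mid - w // 2, "end": mid - w // 2 + w,
                 "placement": "intron", "gene": g.gene_id}
            )
    n_distal = cfg.n_consensus_peaks - len(universe)
    if n_distal < 0:
        raise ValueError("n_consensus_peaks smaller than the gene-linked peak count")
    if n_distal > len(distal_slots):
        raise ValueError(f"not enough distal slots ({len(distal_slots)}) for {n_distal} distal peaks")
    for chrom, pos in distal_slots[:n_distal]:
        start = pos + (cfg.enhancer_width + 50 - w) // 2
        universe.append({"chrom": chrom, "start": start, "end": start + w, "placement": "distal", "gene": ""})

    # differential assignment: every classified gene's promoter peak, then
    # extra distal regions until frac_differential is reached
    n_diff = int(round(cfg.frac_differential * len(universe)))
    if n_diff < 1:
        import warnings

        warnings.warn("frac_differential x n_consensus_peaks < 1: zero differential regions planted")
    gene_order = {gid: i for i, gid in enumerate(gene_ids)}
    n_assigned = 0
    extra_cells = [cfg.cell_types[i % len(cfg.cell_types)] for i in range(len(universe))]
    n_extra = 0
    for p in universe:
        p["differential"] = False
        p["enriched_in"] = ""
        p["log2fc"] = 0.0
    for p in universe:
        if p["placement"] == "promoter" and p["gene"] in truth.gene_classes and n_assigned < n_diff:
            gid = p["gene"]
            cell = _enriched_cell_for(gid, truth.gene_classes[gid], gene_order[gid])
            p.update(differential=True, enriched_in=cell, log2fc=cfg.planted_log2fc)
            truth.gene_enriched_cell[gid] = cell
            n_assigned += 1
    for p in universe:
        if n_assigned >= n_diff:
            break
        if p["placement"] == "distal" and not p["differential"]:
            p.update(differential=True, enriched_in=extra_cells[n_extra], log2fc=cfg.planted_log2fc)
            n_extra += 1
            n_assigned += 1
    truth.peaks = universe

    # per-sample emission
    total_bp = sum(cfg.chrom_sizes.values())
    chrom_names = sorted(cfg.chrom_sizes)
    chrom_offsets = np.cumsum([0] + [cfg.chrom_sizes[c] for c in chrom_names])
    paths: dict = {"atac": {}, "fragments": {}}
    enh_active = [e for e in truth.enhancers if e["state"] == "active"]
    for cell, rep in cfg.samples:
        rows = []
        mean_list = []
        for p in universe:
            if rng.random() > cfg.observation_prob:
                continue
            mean = cfg.mean_count * (2.0 ** cfg.planted_log2fc if p["enriched_in"] == cell else 1.0)
            rows.append((p["chrom"], p["start"], p["end"], mean))
            mean_list.append(mean)
        for e in enh_active:
            if cell in e["cells"]:
                mid = (e["start"] + e["end"]) // 2
                rows.append((e["chrom"], mid - w // 2, mid - w // 2 + w, cfg.mean_count))
                mean_list.append(cfg.mean_count)
        counts = _nb_draw(rng, np.asarray(mean_list), cfg.nb_dispersion)

        peak_path = outdir / "atac" / f"{cell}_{rep}.narrowPeak"
        rs = RegionSet(
            [
                GenomicInterval(c, s, e, name=f"{cell}_{rep}_pk{i}", score=float(np.round(m, 2)))
                for i, (c, s, e, m) in enumerate(rows)
            ],
            meta={"cell_type": cell, "replicate": rep, "track_kind": "atac"},
        )
        write_regions(rs, peak_path, format="narrowpeak")
        paths["atac"][(cell, rep)] = peak_path

        # fragments: peak fragments at drawn counts + uniform background
        frag_chrom: list[str] = []
        frag_mid: list[np.ndarray] = []
        for (c, s, e, m), n_frag in zip(rows, counts):
            if n_frag == 0:
                continue
            frag_chrom.extend([c] * int(n_frag))
            frag_mid.append(rng.integers(s, e, size=int(n_frag)))
        mids = np.concatenate(frag_mid) if frag_mid else np.zeros(0, dtype=np.int64)
        n_peak_frags = len(mids)
        n_bg = int(round(n_peak_frags * (1.0 - cfg.frip_target) / cfg.frip_target))
        bg_gpos = rng.integers(0, total_bp, size=n_bg)
        bg_idx = np.searchsorted(chrom_offsets, bg_gpos, side="right") - 1
        bg_mid = bg_gpos - chrom_offsets[bg_idx]
        bg_chrom = [chrom_names[i] for i in bg_idx]
        all_chrom = np.asarray(frag_chrom + bg_chrom)
        all_mid = np.concatenate([mids, bg_mid])
        half = cfg.fragment_length // 2
        starts = np.maximum(all_mid - half, 0)
        ends = starts + cfg.fragment_length
        df = pd.DataFrame({"chrom": all_chrom, "start": starts, "end": ends})
        df = df.sort_values(["chrom", "start", "end"], kind="stable").reset_index(drop=True)
        df["name"] = [f"f{i}" for i in range(len(df))]
        frag_path = outdir / "fragments" / f"{cell}_{rep}.bed"
        df.to_csv(frag_path, sep="\t", header=False, index=False)
        paths["fragments"][(cell, rep)] = frag_path
    return paths


# ---------------------------------------------------------------------------
# expression
# ---------------------------------------------------------------------------

_TF_RPKM = {
    "Pdx1": {"alpha": 0.0, "beta": 15.0, "delta": 8.0},
    "Nkx6-1": {"alpha": 0.0, "beta": 12.0, "delta": 0.0},
    "Neurod1": {"alpha": 5.0, "beta": 10.0, "delta": 5.0},
    "Insm1": {"alpha": 6.0, "beta": 8.0, "delta": 6.0},
    "Foxa2": {"alpha": 7.0, "beta": 7.0, "delta": 7.0},
    "Nkx2-2": {"alpha": 4.0, "beta": 6.0, "delta": 4.0},
    "Rfx6": {"alpha": 3.0, "beta": 6.0, "delta": 3.0},
    "Mafa": {"alpha": 0.0, "beta": 20.0, "delta": 0.0},
}


def generate_expression(
    cfg: SyntheticConfig,
    genes: list[Gene],
    truth: TruthManifest,
    outdir: str | Path,
) -> tuple[Path, Path]:
    """Emit the RPKM table (+ transdifferentiated columns) and the companion
    expression differential table for the alpha-vs-beta axis.

    Class archetypes (before optional multiplicative noise):
    congruent: 20 in the peak-enriched cell vs 1; repressed: 0.1 in the
    peak cell vs 20; poised repressed genes get the stepwise
    (origin, transdiff, beta) = (0.1, 5, 20) pattern, transition genes
    (0.1, 20, 5); unexpressed: 0 in both compared cells. TF marker genes are
    appended with fixed profiles for the motif expression filter.
    """
    outdir = Path(outdir)
    rng = np.random.default_rng([cfg.seed, _RNG_EXPRESSION])
    if not truth.gene_classes:
        raise ValueError("gene classes must be assigned before expression generation")
    cols = ["alpha", "beta", "delta", "alpha_transdiff", "delta_transdiff"]
    rows = {}
    poised = set(truth.poised_genes)
    transition = set(truth.transition_genes)
    for g in genes:
        klass = truth.gene_classes[g.gene_id]
        base = {c: 1.0 for c in cols}
        if klass == "congruent_in_alpha":
            base.update(alpha=20.0, beta=1.0)
        elif klass == "congruent_in_beta":
            base.update(alpha=1.0, beta=20.0)
        elif klass == "repressed_in_alpha":
            if g.gene_id in poised:
                base.update(alpha=0.1, alpha_transdiff=5.0, beta=20.0)
            elif g.gene_id in transition:
                base.update(alpha=0.1, alpha_transdiff=20.0, beta=5.0)
            else:
                base.update(alpha=0.1, beta=20.0)
        elif klass == "repressed_in_beta":
            base.update(alpha=20.0, beta=0.1)
        else:  # unexpressed on the compared axis
            base.update(alpha=0.0, beta=0.0, delta=0.5)
        if cfg.expression_noise_sd > 0:
            noise = np.exp(rng.normal(0.0, cfg.expression_noise_sd, size=len(cols)))
            base = {c: v * n for (c, v), n in zip(base.items(), noise)}
        rows[g.gene_id] = base
    for tf in cfg.tf_names:
        prof = _TF_RPKM.get(tf, {"alpha": 2.0, "beta": 2.0, "delta": 2.0})
        rows[tf] = {
            "alpha": prof["alpha"], "beta": prof["beta"], "delta": prof["delta"],
            "alpha_transdiff": 1.0, "delta_transdiff": 1.0,
        }
    expr = pd.DataFrame.from_dict(rows, orient="index")[cols]
    expr.index.name = "gene"
    expr_path = outdir / "expression.tsv"
    expr.to_csv(expr_path, sep="\t", float_format="%.6g")

    de = pd.DataFrame(
        {
            "log2fc": np.log2(expr["alpha"] + 0.5) - np.log2(expr["beta"] + 0.5),
            "q_value": [
                1.0 if truth.gene_classes.get(g) == "unexpressed" else 0.001
                for g in expr.index
            ],
        }
    )
    de.index.name = "gene"
    de_path = outdir / "expression_de_alpha_vs_beta.tsv"
    de.to_csv(de_path, sep="\t", float_format="%.6g")
    return expr_path, de_path


# ---------------------------------------------------------------------------
# epigenome (histone, TF, catalog tracks)
# ---------------------------------------------------------------------------

def generate_epigenome(cfg: SyntheticConfig, truth: TruthManifest, outdir: str | Path) -> dict:
    """Emit H3K27ac/H3K4me1/H3K4me3, TF ChIP and catalog BED tracks from the plan.

    Planted active enhancers carry both activating marks (H3K4me1 slightly
    padded) plus their configured TF peaks; poised regions carry H3K4me1
    only; active-promoter regions carry H3K4me3 (+H3K27ac); decoys carry the
    incomplete combinations recorded in the manifest.
    """
    outdir = Path(outdir)
    (outdir / "chip").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, _RNG_EPIGENOME])
    h3k27ac, h3k4me1, h3k4me3, catalog = [], [], [], []
    tf_peaks: dict[str, list[GenomicInterval]] = {tf: [] for tf in cfg.tf_names}

    def tf_peak(chrom: str, s: int, e: int) -> GenomicInterval:
        width = 150
        lo, hi = s, max(s + 1, e - width)
        start = int(rng.integers(lo, hi + 1))
        return GenomicInterval(chrom, start, start + width)

    for e in truth.enhancers:
        region = GenomicInterval(e["chrom"], e["start"], e["end"])
        padded = GenomicInterval(e["chrom"], e["start"] - 25, e["end"] + 25)
        if e["state"] == "active":
            h3k27ac.append(region)
            h3k4me1.append(padded)
            for tf in e["tfs"]:
                tf_peaks[tf].append(tf_peak(e["chrom"], e["start"], e["end"]))
            if e["catalog"]:
                catalog.append(region)
        elif e["state"] == "poised":
            h3k4me1.append(region)
        elif e["state"] == "active_promoter":
            h3k4me3.append(region)
            h3k27ac.append(region)
    for d in truth.decoys:
        region = GenomicInterval(d["chrom"], d["start"], d["end"])
        kind = d["kind"]
        if kind == "h3k27ac_only":
            h3k27ac.append(region)
            tf_peaks[cfg.tf_names[0]].append(tf_peak(d["chrom"], d["start"], d["end"]))
        elif kind == "h3k4me1_only":
            h3k4me1.append(region)
            tf_peaks[cfg.tf_names[0]].append(tf_peak(d["chrom"], d["start"], d["end"]))
        elif kind == "histones_no_tf":
            h3k27ac.append(region)
            h3k4me1.append(region)
        elif kind == "tf_only":
            tf_peaks[cfg.tf_names[0]].append(tf_peak(d["chrom"], d["start"], d["end"]))
        elif kind == "catalog_only":
            catalog.append(region)

    paths: dict = {"histone": {}, "tf": {}}
    for name, items in (("H3K27ac", h3k27ac), ("H3K4me1", h3k4me1), ("H3K4me3", h3k4me3)):
        p = outdir / "chip" / f"{name}.bed"
        write_regions(RegionSet(items, meta={"track_kind": "histone", "label": name}), p)
        paths["histone"][name] = p
    for tf in cfg.tf_names:
        p = outdir / "chip" / f"{tf}.bed"
        write_regions(RegionSet(tf_peaks[tf], meta={"track_kind": "chip_tf", "label": tf}), p)
        paths["tf"][tf] = p
    cat_path = outdir / "catalog.bed"
    write_regions(RegionSet(catalog, meta={"track_kind": "enhancer_catalog", "label": "catalog"}), cat_path)
    paths["catalog"] = cat_path
    return paths


# ---------------------------------------------------------------------------
# motif sequences
# ---------------------------------------------------------------------------

def consensus_counts(consensus: str, hit: float = 97.0, miss: float = 1.0) -> np.ndarray:
    mat = np.full((4, len(consensus)), miss)
    for j, b in enumerate(consensus):
        mat["ACGT".index(b), j] = hit
    return mat


def generate_motif_sequences(cfg: SyntheticConfig, truth: TruthManifest, outdir: str | Path) -> dict:
    """Emit planted-motif FASTA, JASPAR-style .pfm files and the motif->TF map.

    Background sequences are i.i.d. uniform ACGT; for each motif,
    round(plant_rate x n) sequences receive one exact consensus instance at
    a recorded offset and strand (each sequence carries at most one plant).
    """
    from .motifs import reverse_complement

    outdir = Path(outdir)
    (outdir / "motifs").mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng([cfg.seed, _RNG_MOTIFS])
    n, L = cfg.n_motif_sequences, cfg.motif_sequence_length
    for spec in cfg.motif_set:
        if len(spec.consensus) > L:
            raise ValueError(f"motif {spec.motif_id} longer than sequence length {L}")
    bases = np.array(list("ACGT"))
    seqs = ["".join(bases[rng.integers(0, 4, size=L)]) for _ in range(n)]
    names = [f"seq{i + 1:04d}" for i in range(n)]

    plant_counts = [int(round(spec.plant_rate * n)) for spec in cfg.motif_set]
    if sum(plant_counts) > n:
        raise ValueError("total motif plant rates exceed the number of sequences")
    cursor = 0
    for spec, n_plant in zip(cfg.motif_set, plant_counts):
        m = len(spec.consensus)
        for _ in range(n_plant):
            name = names[cursor]
            offset = int(rng.integers(0, L - m + 1))
            strand = "+" if rng.random() < 0.5 else "-"
            inserted = spec.consensus if strand == "+" else reverse_complement(spec.consensus)
            s = seqs[cursor]
            seqs[cursor] = s[:offset] + inserted + s[offset + m :]
            truth.motif_plants[name] = {"motif_id": spec.motif_id, "offset": offset, "strand": strand}
            cursor += 1

    fasta = outdir / "motifs" / "sequences.fa"
    with open(fasta, "w") as fh:
        for name, s in zip(names, seqs):
            fh.write(f">{name}\n{s}\n")
    pwm_paths = {}
    for spec in cfg.motif_set:
        counts = consensus_counts(spec.consensus)
        p = outdir / "motifs" / f"{spec.motif_id}.pfm"
        with open(p, "w") as fh:
            fh.write(f">{spec.motif_id} {spec.tf_name}\n")
            for b, row in zip("ACGT", counts):
                fh.write(b + "  " + "  ".join(f"{v:g}" for v in row) + "\n")
        pwm_paths[spec.motif_id] = p
    map_path = outdir / "motifs" / "motif_map.tsv"
    with open(map_path, "w") as fh:
        fh.write("motif_id\ttf\n")
        for spec in cfg.motif_set:
            fh.write(f"{spec.motif_id}\t{spec.tf_name}\n")
    return {"fasta": fasta, "pwms": pwm_paths, "motif_map": map_path}


# ---------------------------------------------------------------------------
# orchestration + direct count-matrix simulation
# ---------------------------------------------------------------------------

def generate_world(cfg: SyntheticConfig, outdir: str | Path) -> World:
    """Generate the complete synthetic world into ``outdir``.

    Stages run annotation -> enhancer plan -> accessibility -> expression ->
    epigenome -> motif sequences; the truth manifest and a config echo are
    written as JSON at the end.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    truth = TruthManifest()
    genes, gtf, tss_bed = generate_annotation(cfg, outdir)
    gene_ids = [g.gene_id for g in genes]
    truth.gene_classes, truth.poised_genes, truth.transition_genes = partition_gene_classes(cfg, gene_ids)
    remaining_slots = plan_enhancers(cfg, genes, truth)
    _catalog_fraction_exact(cfg, truth)
    acc_paths = generate_accessibility(cfg, genes, truth, outdir, distal_slots=remaining_slots)
    expr_path, de_path = generate_expression(cfg, genes, truth, outdir)
    epi_paths = generate_epigenome(cfg, truth, outdir)
    motif_paths = generate_motif_sequences(cfg, truth, outdir)
    truth_path = truth.to_json(outdir / "truth.json")
    cfg_echo = dataclasses.asdict(cfg)
    cfg_echo["motif_set"] = [dataclasses.asdict(m) for m in cfg.motif_set]
    (outdir / "config.json").write_text(json.dumps(cfg_echo, indent=2, sort_keys=True, default=str))
    paths = {
        "gtf": gtf,
        "tss_bed": tss_bed,
        "expression": expr_path,
        "expression_de": de_path,
        "truth": truth_path,
        **acc_paths,
        **epi_paths,
        **motif_paths,
    }
    return World(cfg=cfg, outdir=outdir, genes=genes, truth=truth, paths=paths)


def simulate_count_matrix(
    n_regions: int,
    group_sizes: dict[str, int],
    mean_count: float = 100.0,
    dispersion: float = 0.05,
    log2fc: float = 2.0,
    frac_differential: float = 0.0,
    seed: int = 0,
) -> tuple[CountMatrix, pd.DataFrame]:
    """Directly simulate an NB count matrix with planted differential regions.

    The first round(frac_differential x n_regions) regions are enriched
    (mean x 2^log2fc) in one group, cycling through the groups; all library
    sizes are padded by a 20% off-region share so TMM and effective library
    sizes behave as with real fragment files. Returns (CountMatrix, truth
    table with columns differential/enriched_in).
    """
    rng = np.random.default_rng(seed)
    cells = sorted(group_sizes)
    samples = [(c, f"r{i + 1}") for c in cells for i in range(group_sizes[c])]
    n_diff = int(round(frac_differential * n_regions))
    enriched = ["" for _ in range(n_regions)]
    for i in range(n_diff):
        enriched[i] = cells[i % len(cells)]
    means = np.full((n_regions, len(samples)), float(mean_count))
    for i, cell in enumerate(enriched):
        if cell:
            for s, (c, _) in enumerate(samples):
                if c == cell:
                    means[i, s] *= 2.0 ** log2fc
    counts = _nb_draw(rng, means, dispersion)
    regions = [
        GenomicInterval("chrS", 1000 * i, 1000 * i + 500, name=f"sim{i}") for i in range(n_regions)
    ]
    lib_sizes = counts.sum(axis=0) * 1.2
    cm = CountMatrix(regions=regions, samples=samples, counts=counts, lib_sizes=lib_sizes)
    tr = pd.DataFrame(
        {"differential": [bool(e) for e in enriched], "enriched_in": enriched},
        index=[r.name for r in regions],
    )
    return cm, tr
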