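"""Peak-to-genome annotation, category distributions, TSS profiles, and FRiP QC.

Every peak is assigned exactly one functional category by a fixed precedence
(promoter_proximal > exon > first_intron > other_intron > downstream >
distal_intergenic). The lookup uses the peak midpoint first; a peak whose
midpoint falls in no feature but which still overlaps one is resolved by the
same precedence over any-overlap. This makes the category a function of the
peak and keeps percentages additive.

The promoter window is symmetric (TSS +/- ``promoter_window`` bp) by default,
with an upstream-only mode behind a flag; "downstream" is a strand-aware
window past the annotated 3' end. UTR bases count as exonic (no separate UTR
categories).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genes import Gene
from .intervals import (
    GenomicInterval,
    RegionSet,
    as_point_arrays,
    coverage_bp,
    merge_regions,
    overlap_mask,
    points_in_regions,
    subtract_regions,
)

CATEGORIES = (
    "promoter_proximal",
    "exon",
    "first_intron",
    "other_intron",
    "downstream",
    "distal_intergenic",
)

FRIP_BENCHMARK = 0.3


@dataclass
class FeatureIndex:
    """Genome partition features derived from gene models."""

    promoters: RegionSet
    exons: RegionSet
    first_introns: RegionSet
    other_introns: RegionSet
    downstream: RegionSet
    genome_bp: dict[str, int]
    genes: list[Gene]

    def feature_sets(self) -> dict[str, RegionSet]:
        return {
            "promoter_proximal": self.promoters,
            "exon": self.exons,
            "first_intron": self.first_introns,
            "other_intron": self.other_introns,
            "downstream": self.downstream,
        }


@dataclass
class AnnotatedPeak:
    interval: GenomicInterval
    category: str
    nearest_gene: str
    tss_distance: float  # signed bp, negative = upstream of the nearest TSS


@dataclass
class QCMetrics:
    frip: float
    n_fragments: int
    n_in_peaks: int
    passed: bool


def build_feature_index(
    genes: list[Gene],
    promoter_window: int = 3000,
    downstream_window: int = 3000,
    genome_bp: dict[str, int] | None = None,
    upstream_only: bool = False,
) -> FeatureIndex:
    """Derive promoter/exon/intron/downstream features from gene models.

    Introns are the gaps between consecutive exons; the intron adjacent to
    the TSS-proximal exon is "first". Single-exon genes contribute no introns.
    """
    if genome_bp is None:
        genome_bp = {}
        for g in genes:
            genome_bp[g.chrom] = max(genome_bp.get(g.chrom, 0), g.end + downstream_window + promoter_window)

    promoters, exons, first_introns, other_introns, downstream = [], [], [], [], []
    for g in genes:
        L = genome_bp.get(g.chrom)
        if upstream_only:
            if g.strand == "+":
                ps, pe = g.tss - promoter_window, g.tss + 1
            else:
                ps, pe = g.tss, g.tss + promoter_window + 1
        else:
            ps, pe = g.tss - promoter_window, g.tss + promoter_window
        ps = max(0, ps)
        if L is not None:
            pe = min(pe, L)
        if ps < pe:
            promoters.append(GenomicInterval(g.chrom, ps, pe, name=g.gene_id, strand=g.strand))
        for (s, e) in g.exons:
            exons.append(GenomicInterval(g.chrom, s, e, name=g.gene_id, strand=g.strand))
        gaps = g.introns()
        if gaps:
            first_idx = 0 if g.strand == "+" else len(gaps) - 1
            for i, (s, e) in enumerate(gaps):
                target = first_introns if i == first_idx else other_introns
                target.append(GenomicInterval(g.chrom, s, e, name=g.gene_id, strand=g.strand))
        if g.strand == "+":
            ds, de = g.end, g.end + downstream_window
        else:
            ds, de = g.start - downstream_window, g.start
        ds = max(0, ds)
        if L is not None:
            de = min(de, L)
        if ds < de:
            downstream.append(GenomicInterval(g.chrom, ds, de, name=g.gene_id, strand=g.strand))

    return FeatureIndex(
        promoters=RegionSet(promoters),
        exons=RegionSet(exons),
        first_introns=RegionSet(first_introns),
        other_introns=RegionSet(other_introns),
        downstream=RegionSet(downstream),
        genome_bp=dict(genome_bp),
        genes=list(genes),
    )


def _nearest_tss(peaks: RegionSet, genes: list[Gene]) -> tuple[list[str], np.ndarray]:
    by_chrom: dict[str, tuple[np.ndarray, list[str], list[str]]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, ([], [], []))  # type: ignore[arg-type]
    tmp: dict[str, tuple[list, list, list]] = {c: ([], [], []) for c in by_chrom}
    for g in genes:
        t, ids, strands = tmp[g.chrom]
        t.append(g.tss)
        ids.append(g.gene_id)
        strands.append(g.strand)
    sorted_tbl = {}
    for c, (t, ids, strands) in tmp.items():
        order = np.argsort(np.asarray(t, dtype=np.int64), kind="stable")
        sorted_tbl[c] = (
            np.asarray(t, dtype=np.int64)[order],
            [ids[i] for i in order],
            [strands[i] for i in order],
        )

    names: list[str] = []
    dists = np.full(len(peaks), np.nan)
    for i, iv in enumerate(peaks):
        tbl = sorted_tbl.get(iv.chrom)
        if tbl is None or len(tbl[0]) == 0:
            names.append("")
            continue
        t, ids, strands = tbl
        mid = iv.midpoint
        j = int(np.searchsorted(t, mid))
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(t):
                d = abs(mid - int(t[k]))
                if best is None or d < best[0]:
                    best = (d, k)
        k = best[1]
        names.append(ids[k])
        signed = mid - int(t[k]) if strands[k] == "+" else int(t[k]) - mid
        dists[i] = signed
    return names, dists


def classify_peaks(peaks: RegionSet, idx: FeatureIndex) -> list[AnnotatedPeak]:
    """Assign each peak exactly one category; always report nearest gene + signed TSS distance."""
    n = len(peaks)
    chroms = np.asarray([iv.chrom for iv in peaks])
    mids = np.asarray([iv.midpoint for iv in peaks], dtype=np.int64)
    cats = np.full(n, "", dtype=object)

    for cat, fs in idx.feature_sets().items():
        if len(fs) == 0:
            continue
        undecided = cats == ""
        if not undecided.any():
            break
        hit = points_in_regions(chroms[undecided], mids[undecided], fs)
        where = np.flatnonzero(undecided)[hit]
        cats[where] = cat

    # fallback: any-overlap under the same precedence
    undecided_idx = np.flatnonzero(cats == "")
    if undecided_idx.size:
        sub = RegionSet.__new__(RegionSet)
        sub.intervals = [peaks[int(i)] for i in undecided_idx]
        sub.meta = {}
        sub._by_chrom = None
        remaining = np.ones(len(undecided_idx), dtype=bool)
        for cat, fs in idx.feature_sets().items():
            if len(fs) == 0 or not remaining.any():
                continue
            hit = overlap_mask(sub, fs) & remaining
            cats[undecided_idx[hit]] = cat
            remaining &= ~hit
        cats[undecided_idx[remaining]] = "distal_intergenic"
    cats[cats == ""] = "distal_intergenic"

    names, dists = _nearest_tss(peaks, idx.genes)
    return [
        AnnotatedPeak(iv, str(cats[i]), names[i], float(dists[i]))
        for i, iv in enumerate(peaks)
    ]


def genome_background(idx: FeatureIndex) -> pd.Series:
    """Genome base fractions (%) per category under the precedence partition."""
    total = sum(idx.genome_bp.values())
    claimed = RegionSet([])
    bp = {}
    for cat, fs in idx.feature_sets().items():
        remaining = subtract_regions(fs, claimed) if len(claimed) else merge_regions(fs)
        bp[cat] = coverage_bp(remaining)
        claimed = merge_regions(RegionSet(list(claimed) + list(remaining)))
    bp["distal_intergenic"] = total - sum(bp.values())
    return pd.Series({c: 100.0 * bp[c] / total for c in CATEGORIES})


def category_distribution(annotated: list[AnnotatedPeak], idx: FeatureIndex) -> pd.DataFrame:
    """Per-category peak percentages next to genome-background percentages.

    Both columns sum to 100 (peak percentages are 0 for an empty input).
    """
    counts = pd.Series(0, index=list(CATEGORIES), dtype=int)
    for ap in annotated:
        counts[ap.category] += 1
    n = counts.sum()
    peak_pct = 100.0 * counts / n if n else counts.astype(float)
    return pd.DataFrame(
        {"n_peaks": counts, "peak_pct": peak_pct, "genome_pct": genome_background(idx)}
    )


def tss_profile(peaks: RegionSet, tss: RegionSet, flank: int = 3000, bins: int = 60) -> np.ndarray:
    """Binned density of peak midpoints around TSSs, strand-oriented.

    Each peak midpoint within +/- flank of its nearest TSS contributes one
    count; the vector sums to the number of counted midpoints.
    """
    if bins < 1:
        raise ValueError("bins must be >= 1")
    profile = np.zeros(bins, dtype=np.int64)
    tss_by_chrom: dict[str, tuple[np.ndarray, list[str]]] = {}
    for c, (s, _, idxs) in tss.by_chrom().items():
        tss_by_chrom[c] = (s, [tss[i].strand for i in idxs])
    width = 2.0 * flank / bins
    for iv in peaks:
        tbl = tss_by_chrom.get(iv.chrom)
        if tbl is None:
            continue
        positions, strands = tbl
        mid = iv.midpoint
        j = int(np.searchsorted(positions, mid))
        best = None
        for k in (j - 1, j):
            if 0 <= k < len(positions):
                d = abs(mid - int(positions[k]))
                if best is None or d < best[0]:
                    best = (d, k)
        if best is None or best[0] > flank:
            continue
        k = best[1]
        offset = mid - int(positions[k])
        if strands[k] == "-":
            offset = -offset
        b = int((offset + flank) // width)
        profile[min(max(b, 0), bins - 1)] += 1
    return profile


def compute_frip(fragments, peaks: RegionSet, benchmark: float = FRIP_BENCHMARK) -> QCMetrics:
    """Fraction of fragments whose midpoint falls inside the merged peak set.

    ``fragments`` may be a RegionSet or a fragment DataFrame (see
    :func:`isletkit.intervals.read_fragment_table`); ``passed`` is True iff
    FRiP >= the ENCODE-style benchmark (default 0.3).
    """
    if len(fragments) == 0:
        raise ValueError("FRiP is undefined for an empty fragment set")
    chroms, mids = as_point_arrays(fragments)
    inside = points_in_regions(chroms, mids, peaks) if len(peaks) else np.zeros(len(fragments), bool)
    n_in = int(inside.sum())
    frip = n_in / len(fragments)
    return QCMetrics(frip=frip, n_fragments=len(fragments), n_in_peaks=n_in, passed=frip >= benchmark)
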