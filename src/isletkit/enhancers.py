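"""Rule-based enhancer identification from co-localized histone marks, TF
binding, open chromatin, and a curated enhancer catalog.

The calling chain:

1. putative — base-level intersection of the merged H3K27ac and H3K4me1
   tracks (the maximal co-marked span), kept only where at least one TF ChIP
   track overlaps; the co-binding count is the number of distinct TF tracks
   overlapping (a per-peak variant counts every overlapping ChIP interval).
2. active — putative calls overlapping at least one cell type's open-
   chromatin consensus; accessibility per cell is recorded.
3. conservative — active calls additionally supported by the curated
   enhancer catalog.

Regions overlapping H3K4me3 are classed as active promoters and excluded
from enhancer lists; H3K4me1 without H3K27ac marks a poised enhancer.
Enrichment of region co-localization over chance is assessed with a
length-preserving uniform re-placement permutation test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .intervals import (
    GenomicInterval,
    RegionSet,
    intersection_regions,
    overlap_mask,
)

SPECIFICITY_CLASSES = (
    "common_all",
    "pair_ab",
    "pair_ad",
    "pair_bd",
    "unique_alpha",
    "unique_beta",
    "unique_delta",
)


@dataclass
class EnhancerCall:
    region: GenomicInterval
    cobinding_count: int
    tf_list: tuple[str, ...]
    state: str = "active"  # poised | active | active_promoter
    accessible_in: frozenset = field(default_factory=frozenset)
    catalog_supported: bool = False
    specificity: str = "inaccessible"


@dataclass
class PermutationResult:
    observed_overlap: int
    null_mean: float
    null_sd: float
    z: float
    p_empirical: float
    n_perm: int
    seed: int


def specificity_class(accessible_in: frozenset, cells: tuple[str, str, str] = ("alpha", "beta", "delta")) -> str:
    a, b, d = cells
    s = accessible_in
    if not s:
        return "inaccessible"
    if s == {a, b, d}:
        return "common_all"
    if s == {a, b}:
        return "pair_ab"
    if s == {a, d}:
        return "pair_ad"
    if s == {b, d}:
        return "pair_bd"
    if s == {a}:
        return "unique_alpha"
    if s == {b}:
        return "unique_beta"
    if s == {d}:
        return "unique_delta"
    raise ValueError(f"accessibility set {set(s)} is not a subset of {cells}")


def call_putative(
    h3k27ac: RegionSet,
    h3k4me1: RegionSet,
    tf_tracks: dict[str, RegionSet],
    count_mode: str = "track",
) -> list[EnhancerCall]:
    """First-pass putative enhancers: H3K27ac AND H3K4me1 AND >= 1 TF track.

    Candidates are the base-level intersection intervals of the two merged
    histone tracks. ``count_mode='track'`` counts each overlapping TF track
    once; ``'peak'`` counts every overlapping ChIP interval. Output is sorted
    by co-binding count descending, then coordinate.
    """
    if not tf_tracks:
        raise ValueError("at least one TF ChIP track is required by the enhancer definition")
    if count_mode not in ("track", "peak"):
        raise ValueError("count_mode must be 'track' or 'peak'")
    candidates = intersection_regions(h3k27ac, h3k4me1)
    if len(candidates) == 0:
        return []
    counts = np.zeros(len(candidates), dtype=np.int64)
    tf_hits: list[list[str]] = [[] for _ in range(len(candidates))]
    for tf_name in sorted(tf_tracks):
        track = tf_tracks[tf_name]
        if count_mode == "track":
            mask = overlap_mask(candidates, track)
            counts += mask.astype(np.int64)
            for i in np.flatnonzero(mask):
                tf_hits[i].append(tf_name)
        else:
            per_peak = np.zeros(len(candidates), dtype=np.int64)
            for iv in track:
                single = RegionSet([iv])
                per_peak += overlap_mask(candidates, single).astype(np.int64)
            counts += per_peak
            for i in np.flatnonzero(per_peak):
                tf_hits[i].append(tf_name)
    calls = [
        EnhancerCall(region=iv, cobinding_count=int(counts[i]), tf_list=tuple(tf_hits[i]))
        for i, iv in enumerate(candidates)
        if counts[i] >= 1
    ]
    calls.sort(key=lambda c: (-c.cobinding_count, c.region.chrom, c.region.start, c.region.end))
    return calls


def filter_accessible(
    calls: list[EnhancerCall],
    atac_by_cell: dict[str, RegionSet],
    cells: tuple[str, str, str] = ("alpha", "beta", "delta"),
) -> tuple[list[EnhancerCall], list[EnhancerCall]]:
    """Populate per-cell accessibility; retain calls open in >= 1 cell type.

    Returns (all calls with accessibility annotated, accessible subset).
    """
    unknown = set(atac_by_cell) - set(cells)
    if unknown:
        raise ValueError(f"unknown cell keys in atac_by_cell: {sorted(unknown)}")
    if not calls:
        return [], []
    regions = RegionSet([c.region for c in calls])
    key_to_call = {c.region.sort_key(): c for c in calls}
    masks = {}
    for cell, consensus in atac_by_cell.items():
        m = overlap_mask(regions, consensus)
        masks[cell] = {iv.sort_key(): bool(m[i]) for i, iv in enumerate(regions)}
    for c in calls:
        k = c.region.sort_key()
        acc = frozenset(cell for cell in atac_by_cell if masks[cell][k])
        c.accessible_in = acc
        c.specificity = specificity_class(acc, cells)
    active = [c for c in calls if c.accessible_in]
    return calls, active


def filter_catalog(calls: list[EnhancerCall], catalog: RegionSet) -> list[EnhancerCall]:
    """Flag catalog support; return the conservative (catalog-supported) subset."""
    if not calls:
        return []
    regions = RegionSet([c.region for c in calls])
    m = overlap_mask(regions, catalog) if len(catalog) else np.zeros(len(regions), dtype=bool)
    flag = {iv.sort_key(): bool(m[i]) for i, iv in enumerate(regions)}
    for c in calls:
        c.catalog_supported = flag[c.region.sort_key()]
    return [c for c in calls if c.catalog_supported]


def classify_state(
    region: GenomicInterval,
    h3k27ac: RegionSet,
    h3k4me1: RegionSet,
    h3k4me3: RegionSet,
) -> str:
    """Chromatin state of a region from the three histone marks.

    H3K4me3 (promoter mark) takes precedence: active_promoter; otherwise
    H3K27ac + H3K4me1 = active, H3K4me1 alone = poised, anything else none.
    """
    single = RegionSet([region])
    has27 = bool(overlap_mask(single, h3k27ac)[0]) if len(h3k27ac) else False
    has1 = bool(overlap_mask(single, h3k4me1)[0]) if len(h3k4me1) else False
    has3 = bool(overlap_mask(single, h3k4me3)[0]) if len(h3k4me3) else False
    if has3:
        return "active_promoter"
    if has27 and has1:
        return "active"
    if has1:
        return "poised"
    return "none"


def specificity_partition(calls: list[EnhancerCall]) -> pd.DataFrame:
    """Counts and percentages over the seven non-empty accessibility classes.

    Calls with empty accessibility are tallied as ``inaccessible`` but are
    excluded from the percentage base.
    """
    counts = pd.Series(0, index=list(SPECIFICITY_CLASSES) + ["inaccessible"], dtype=int)
    for c in calls:
        counts[c.specificity] += 1
    base = counts[list(SPECIFICITY_CLASSES)].sum()
    pct = pd.Series(0.0, index=counts.index)
    if base:
        pct[list(SPECIFICITY_CLASSES)] = 100.0 * counts[list(SPECIFICITY_CLASSES)] / base
    return pd.DataFrame({"n": counts, "pct": pct})


def overlap_stats(open_chromatin: RegionSet, chip: RegionSet) -> tuple[float, float]:
    """(pct of open regions with >= 1 ChIP overlap, pct of ChIP peaks in open chromatin)."""
    if len(open_chromatin) == 0 or len(chip) == 0:
        raise ValueError("overlap statistics undefined for empty sets")
    pct_open = 100.0 * overlap_mask(open_chromatin, chip).sum() / len(open_chromatin)
    pct_chip = 100.0 * overlap_mask(chip, open_chromatin).sum() / len(chip)
    return float(pct_open), float(pct_chip)


def permutation_enrichment(
    set_a: RegionSet,
    set_b: RegionSet,
    chrom_sizes: dict[str, int],
    n_perm: int = 100,
    seed: int = 0,
) -> PermutationResult:
    """Permutation test of a-over-b overlap against uniform re-placement.

    Each permutation re-places every region of ``set_a`` uniformly at random
    on its own chromosome (length preserved, overlaps between placed regions
    not prevented) and recounts regions overlapping ``set_b``.
    p_empirical = (1 + #{null >= observed}) / (n_perm + 1).
    """
    for iv in set_a:
        size = chrom_sizes.get(iv.chrom)
        if size is None or iv.length > size:
            raise ValueError(f"region {iv.chrom}:{iv.start}-{iv.end} does not fit its chromosome")
    observed = int(overlap_mask(set_a, set_b).sum())
    rng = np.random.default_rng(seed)
    lengths = np.array([iv.length for iv in set_a], dtype=np.int64)
    chroms = [iv.chrom for iv in set_a]
    null = np.zeros(n_perm, dtype=np.int64)
    b_index = set_b.by_chrom()
    for p in range(n_perm):
        count = 0
        placed_starts = np.array(
            [rng.integers(0, chrom_sizes[c] - L + 1) for c, L in zip(chroms, lengths)],
            dtype=np.int64,
        )
        ends = placed_starts + lengths
        for i, c in enumerate(chroms):
            tbl = b_index.get(c)
            if tbl is None:
                continue
            sb, eb, _ = tbl
            ov = np.minimum(ends[i], eb) - np.maximum(placed_starts[i], sb)
            if (ov >= 1).any():
                count += 1
        null[p] = count
    null_mean = float(null.mean())
    null_sd = float(null.std(ddof=1)) if n_perm > 1 else 0.0
    z = (observed - null_mean) / null_sd if null_sd > 0 else 0.0
    p_emp = (1 + int((null >= observed).sum())) / (n_perm + 1)
    return PermutationResult(
        observed_overlap=observed,
        null_mean=null_mean,
        null_sd=null_sd,
        z=float(z),
        p_empirical=float(p_emp),
        n_perm=n_perm,
        seed=seed,
    )


def enhancer_table(calls: list[EnhancerCall]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "chrom": [c.region.chrom for c in calls],
            "start": [c.region.start for c in calls],
            "end": [c.region.end for c in calls],
            "cobinding_count": [c.cobinding_count for c in calls],
            "tf_list": [",".join(c.tf_list) for c in calls],
            "state": [c.state for c in calls],
            "accessible_in": [",".join(sorted(c.accessible_in)) for c in calls],
            "catalog_supported": [c.catalog_supported for c in calls],
            "specificity": [c.specificity for c in calls],
        }
    )
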