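"""Consensus peaks, fragment counting, TMM normalization, and the pairwise
negative-binomial exact test for differential chromatin accessibility.

The testing route mirrors the classic count-based workflow for ATAC
enrichment: replicate peak calls are merged into a consensus (a region must
be supported by at least ``min_replicates`` samples), fragments are counted
per consensus region by the midpoint rule, library composition is corrected
by trimmed-mean-of-M-values (TMM) factors, and each region is tested with a
two-sided exact NB test on counts scaled to a common effective library size.

Deliberate simplifications relative to edgeR: a single common dispersion is
estimated by method of moments (no tagwise empirical-Bayes moderation), and
the equal-library construction scales counts rather than using quantile
adjustment. Significance is the unadjusted p <= alpha (default 0.05); a
Benjamini-Hochberg q-value column is emitted alongside but does not drive
the flag.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import (
    GenomicInterval,
    RegionSet,
    as_point_arrays,
    merge_regions,
    overlap_mask,
)

DEFAULT_ALPHA = 0.05


@dataclass
class CountMatrix:
    """Consensus regions x samples fragment counts with library metadata."""

    regions: list[GenomicInterval]
    samples: list[tuple[str, str]]  # (cell_type, replicate)
    counts: np.ndarray              # shape (n_regions, n_samples), int
    lib_sizes: np.ndarray           # per-sample totals (>= column sums)
    norm_factors: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=np.int64)
        if self.counts.shape != (len(self.regions), len(self.samples)):
            raise ValueError("counts shape must be (n_regions, n_samples)")
        self.lib_sizes = np.asarray(self.lib_sizes, dtype=np.float64)
        if self.norm_factors is None:
            self.norm_factors = np.ones(len(self.samples))
        self.norm_factors = np.asarray(self.norm_factors, dtype=np.float64)
        if (self.norm_factors <= 0).any():
            raise ValueError("norm_factors must be positive")

    def sample_index(self, cell_type: str) -> list[int]:
        return [i for i, (c, _) in enumerate(self.samples) if c == cell_type]

    @property
    def effective_lib_sizes(self) -> np.ndarray:
        return self.lib_sizes * self.norm_factors


@dataclass
class DifferentialPeak:
    region: GenomicInterval
    log2fc: float       # positive = enriched in group A of the comparison
    p_value: float
    q_value: float
    enriched_in: str | None
    significant: bool


def build_consensus(
    replicate_peaks: list[RegionSet],
    min_replicates: int = 2,
    mode: str = "cell",
) -> RegionSet:
    """Merge replicate peak calls; keep regions supported by >= min_replicates samples.

    ``mode='cell'`` (default) requires the support to come from distinct
    replicates of at least one cell type; ``mode='global'`` counts distinct
    supporting samples regardless of cell type. Each peak set's ``meta``
    must carry ``cell_type`` for the cell-wise rule.
    """
    if mode not in ("cell", "global"):
        raise ValueError("mode must be 'cell' or 'global'")
    if min_replicates < 1:
        raise ValueError("min_replicates must be >= 1")
    union = RegionSet([iv for rs in replicate_peaks for iv in rs])
    candidates = merge_regions(union)
    if len(candidates) == 0:
        return candidates

    support: dict[str, np.ndarray] = {}
    for rs in replicate_peaks:
        cell = str(rs.meta.get("cell_type", "")) if mode == "cell" else "__all__"
        hit = overlap_mask(candidates, rs)
        support.setdefault(cell, np.zeros(len(candidates), dtype=np.int64))
        support[cell] += hit.astype(np.int64)
    keep = np.zeros(len(candidates), dtype=bool)
    for counts in support.values():
        keep |= counts >= min_replicates
    kept = [iv for iv, k in zip(candidates.intervals, keep) if k]
    if not kept:
        import warnings

        warnings.warn("consensus is empty: no region reaches min_replicates support")
    return RegionSet(kept, meta={"track_kind": "atac", "label": f"consensus_min{min_replicates}"})


def count_fragments(consensus: RegionSet, fragment_tables: dict[tuple[str, str], object]) -> CountMatrix:
    """Count fragment midpoints per consensus region for each sample.

    ``fragment_tables`` maps (cell_type, replicate) to a fragment DataFrame
    (or RegionSet). A fragment contributes to exactly one region (midpoint
    rule); lib_sizes are the total fragments per sample.
    """
    regions = list(consensus)
    samples = sorted(fragment_tables)
    by_chrom = consensus.by_chrom()
    # regions must be pairwise non-overlapping so the midpoint rule partitions
    for chrom, (starts, ends, _) in by_chrom.items():
        if len(starts) > 1 and (ends[:-1] > starts[1:]).any():
            raise ValueError(f"consensus regions overlap on {chrom}; merge them first")
    counts = np.zeros((len(regions), len(samples)), dtype=np.int64)
    lib_sizes = np.zeros(len(samples))
    for s_i, key in enumerate(samples):
        frags = fragment_tables[key]
        chroms, mids = as_point_arrays(frags)
        lib_sizes[s_i] = len(mids)
        for chrom, (starts, ends, idx) in by_chrom.items():
            sel = chroms == chrom
            if not sel.any():
                continue
            pos = mids[sel]
            k = np.searchsorted(starts, pos, side="right") - 1
            ok = k >= 0
            ok[ok] &= pos[ok] < ends[k[ok]]
            hit_regions, hit_counts = np.unique(k[ok], return_counts=True)
            for r, c in zip(hit_regions, hit_counts):
                counts[idx[int(r)], s_i] += c
    return CountMatrix(regions=regions, samples=samples, counts=counts, lib_sizes=lib_sizes)


def tmm_factors(cm: CountMatrix, trim_m: float = 0.30, trim_a: float = 0.05) -> np.ndarray:
    """Trimmed mean of M-values normalization factors.

    The reference is the highest-depth sample; M and A values are doubly
    trimmed (30% on M, 5% on A by default) and the mean M is weighted by the
    inverse asymptotic (delta-method) variance. Factors are rescaled to
    geometric mean 1.
    """
    counts = cm.counts.astype(float)
    if counts.shape[1] < 2:
        raise ValueError("TMM needs at least two samples")
    lib = counts.sum(axis=0)
    if (lib <= 0).any():
        raise ValueError("every sample must have positive total counts")
    ref = int(np.argmax(lib))
    factors = np.ones(counts.shape[1])
    r = counts[:, ref]
    Nr = lib[ref]
    for s in range(counts.shape[1]):
        if s == ref:
            continue
        x = counts[:, s]
        N = lib[s]
        keep = (x > 0) & (r > 0)
        if keep.sum() == 0:
            factors[s] = 1.0
            continue
        xs, rs = x[keep], r[keep]
        M = np.log2((xs / N) / (rs / Nr))
        A = 0.5 * np.log2((xs / N) * (rs / Nr))
        w = 1.0 / ((N - xs) / (N * xs) + (Nr - rs) / (Nr * rs))
        lo_m, hi_m = np.quantile(M, [trim_m, 1 - trim_m])
        lo_a, hi_a = np.quantile(A, [trim_a, 1 - trim_a])
        sel = (M >= lo_m) & (M <= hi_m) & (A >= lo_a) & (A <= hi_a)
        if sel.sum() == 0:
            sel = np.ones_like(M, dtype=bool)
        factors[s] = 2 ** (np.sum(w[sel] * M[sel]) / np.sum(w[sel]))
    factors = factors / np.exp(np.mean(np.log(factors)))
    return factors


def _common_dispersion(z: np.ndarray, groups: list[np.ndarray]) -> float:
    """Method-of-moments common dispersion on library-scaled counts.

    Per region, pooled within-group mean/variance give phi = (v - m) / m^2;
    the estimate is the across-region mean, floored at 1e-6.
    """
    phis = []
    for row in z:
        num = 0.0
        den = 0.0
        for g in groups:
            vals = row[g]
            m = vals.mean()
            if m <= 0:
                continue
            v = vals.var(ddof=1)
            num += (v - m) * len(vals)
            den += m * m * len(vals)
        if den > 0:
            phis.append(num / den)
    if not phis:
        return 1e-6
    return max(float(np.mean(phis)), 1e-6)


def _exact_nb_pvalue(sum_a: float, sum_b: float, na: int, nb: int, phi: float) -> float:
    """Two-sided exact NB p-value conditional on the total of two group sums.

    Counts are assumed pre-scaled to a common effective library size. The
    group sums are treated as NB with per-sample mean mu = t/(na+nb) and
    dispersion phi (so a sum of k samples has size k/phi). Two-sided
    p = 2 x min(lower tail, upper tail), capped at 1.
    """
    # round each group sum before forming the total: keeps the test exactly
    # symmetric under swapping the groups
    a = int(round(sum_a))
    t = a + int(round(sum_b))
    if t == 0:
        return 1.0
    mu = t / (na + nb)
    size_a, size_b = na / phi, nb / phi
    pa = size_a / (size_a + na * mu)
    pb = size_b / (size_b + nb * mu)
    k = np.arange(t + 1)
    with np.errstate(over="ignore", under="ignore"):
        logw = stats.nbinom.logpmf(k, size_a, pa) + stats.nbinom.logpmf(t - k, size_b, pb)
    logw -= logw.max()
    w = np.exp(logw)
    total = w.sum()
    lower = w[: a + 1].sum() / total
    upper = w[a:].sum() / total
    return float(min(1.0, 2.0 * min(lower, upper)))


def nb_exact_test(
    cm: CountMatrix,
    group_a: str,
    group_b: str,
    alpha: float = DEFAULT_ALPHA,
    prior_count: float = 0.5,
) -> list[DifferentialPeak]:
    """Pairwise exact NB test of group_a vs group_b accessibility per region.

    Positive log2fc means enriched in ``group_a``. ``significant`` is the
    unadjusted p <= alpha; BH q-values are reported for reference.
    """
    ia, ib = cm.sample_index(group_a), cm.sample_index(group_b)
    if not ia or not ib:
        raise ValueError(f"both groups must be present in the count matrix: {group_a}, {group_b}")
    eff = cm.effective_lib_sizes
    common = float(np.exp(np.mean(np.log(eff[ia + ib]))))
    z = cm.counts[:, ia + ib].astype(float) * (common / eff[ia + ib])[None, :]
    ga = np.arange(len(ia))
    gb = np.arange(len(ia), len(ia) + len(ib))
    phi = _common_dispersion(z, [ga, gb])

    mean_a = z[:, ga].mean(axis=1)
    mean_b = z[:, gb].mean(axis=1)
    log2fc = np.log2(mean_a + prior_count) - np.log2(mean_b + prior_count)
    pvals = np.array(
        [
            _exact_nb_pvalue(z[i, ga].sum(), z[i, gb].sum(), len(ia), len(ib), phi)
            for i in range(z.shape[0])
        ]
    )
    qvals = multipletests(pvals, method="fdr_bh")[1]
    out = []
    for i, region in enumerate(cm.regions):
        sig = bool(pvals[i] <= alpha)
        enriched = None
        if sig:
            enriched = group_a if log2fc[i] > 0 else group_b
        out.append(
            DifferentialPeak(
                region=region,
                log2fc=float(log2fc[i]),
                p_value=float(pvals[i]),
                q_value=float(qvals[i]),
                enriched_in=enriched,
                significant=sig,
            )
        )
    return out


def differential_table(peaks: list[DifferentialPeak], comparison: tuple[str, str]) -> pd.DataFrame:
    a, b = comparison
    return pd.DataFrame(
        {
            "chrom": [p.region.chrom for p in peaks],
            "start": [p.region.start for p in peaks],
            "end": [p.region.end for p in peaks],
            "comparison": f"{a}_vs_{b}",
            "log2fc": [p.log2fc for p in peaks],
            "p_value": [p.p_value for p in peaks],
            "q_value": [p.q_value for p in peaks],
            "enriched_in": [p.enriched_in or "" for p in peaks],
            "significant": [p.significant for p in peaks],
        }
    )


def sample_similarity(cm: CountMatrix) -> tuple[pd.DataFrame, pd.DataFrame | None]:
    """Pearson correlation on log2(normalized counts + 1) and first two PCs.

    PCA is skipped (None) with fewer than three samples.
    """
    eff = cm.effective_lib_sizes
    scale = float(np.exp(np.mean(np.log(eff))))
    logz = np.log2(cm.counts.astype(float) * (scale / eff)[None, :] + 1.0)
    labels = [f"{c}_{r}" for c, r in cm.samples]
    corr = pd.DataFrame(np.corrcoef(logz.T), index=labels, columns=labels)
    pcs = None
    if len(cm.samples) >= 3:
        centered = logz.T - logz.T.mean(axis=0)
        u, s, _ = np.linalg.svd(centered, full_matrices=False)
        coords = u[:, :2] * s[:2]
        pcs = pd.DataFrame(coords, index=labels, columns=["PC1", "PC2"])
    return corr, pcs
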