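"""PWM motif scanning with exact score-distribution p-values.

A position count matrix is turned into a probability matrix with a
pseudocount and a log2-odds matrix against the background (uniform by
default). The null distribution of window scores for a random background
L-mer is computed exactly by dynamic programming over a discretized score
lattice (bin width 0.005 bits), which gives a tail probability for any
score and a score threshold for any p-value cutoff. Scanning scores every
window on both strands and reports windows whose exact tail probability is
at or below the threshold.

Downstream, motif hits on differential peaks feed a per-category Fisher
exact preference test (restricted to transcription factors expressed in the
relevant cell, RPKM > 0), and genome-mapped hits are validated against ChIP
peak sets as true/false positive percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .intervals import GenomicInterval, RegionSet, intersect_any

BASES = "ACGT"
SCORE_BIN_BITS = 0.005
DEFAULT_PSEUDOCOUNT = 0.8
DEFAULT_P_THRESHOLD = 1e-4

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


@dataclass
class PWM:
    motif_id: str
    tf_name: str
    matrix: np.ndarray      # 4 x L column-stochastic probabilities (A,C,G,T)
    background: np.ndarray  # length-4 probabilities
    log_odds: np.ndarray    # 4 x L, log2(matrix / background)

    @property
    def length(self) -> int:
        return self.matrix.shape[1]

    @property
    def consensus(self) -> str:
        return "".join(BASES[i] for i in self.matrix.argmax(axis=0))

    @property
    def max_score(self) -> float:
        return float(self.log_odds.max(axis=0).sum())

    def reverse_complement_log_odds(self) -> np.ndarray:
        return self.log_odds[::-1, ::-1]


@dataclass
class MotifHit:
    interval: GenomicInterval  # coordinates within the scanned sequence/region
    motif_id: str
    strand: str
    score: float
    p_at_score: float


@dataclass
class ValidationRates:
    motif_id: str
    tp_pct: float  # % of ChIP peaks containing >= 1 predicted hit
    fp_pct: float  # % of hit-bearing universe regions with no ChIP overlap
    fn_pct: float  # % of ChIP peaks with no predicted hit (= 100 - tp_pct)
    n_chip: int
    n_universe: int


def pwm_from_counts(
    counts: np.ndarray,
    motif_id: str,
    tf_name: str = "",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    background: np.ndarray | None = None,
) -> PWM:
    """Normalize a 4 x L count matrix into a PWM (pseudocount split by background)."""
    counts = np.asarray(counts, dtype=float)
    if counts.ndim != 2 or counts.shape[0] != 4:
        raise ValueError("count matrix must be 4 x L (rows A,C,G,T)")
    if counts.shape[1] < 4:
        raise ValueError("motif length must be >= 4")
    if background is None:
        background = np.full(4, 0.25)
    background = np.asarray(background, dtype=float)
    probs = (counts + pseudocount * background[:, None]) / (counts.sum(axis=0) + pseudocount)
    log_odds = np.log2(probs / background[:, None])
    return PWM(motif_id, tf_name or motif_id, probs, background, log_odds)


def read_pwm(
    path: str | Path,
    format: str = "jaspar_pfm",
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> PWM:
    """Read a JASPAR .pfm (4 rows = A,C,G,T) or HOCOMOCO .pcm (L rows of 4 columns).

    JASPAR rows may be bare numbers or the ``A [ 1 2 3 ]`` style.
    """
    path = Path(path)
    text = [ln.strip() for ln in path.read_text().splitlines() if ln.strip()]
    if not text:
        raise ValueError(f"{path}: empty motif file")
    motif_id = path.stem
    tf_name = ""
    if text[0].startswith(">"):
        header = text[0][1:].split()
        if header:
            motif_id = header[0]
            if len(header) > 1:
                tf_name = header[1]
        text = text[1:]

    rows = []
    for ln in text:
        ln = ln.strip()
        if format == "jaspar_pfm" and ln[:1].upper() in BASES and not ln[:1].isdigit():
            ln = ln[1:]
        ln = ln.replace("[", " ").replace("]", " ")
        try:
            rows.append([float(x) for x in ln.split()])
        except ValueError as exc:
            raise ValueError(f"{path}: unparseable matrix line {ln!r}") from exc
    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        raise ValueError(f"{path}: ragged count matrix")
    mat = np.asarray(rows, dtype=float)
    if format == "jaspar_pfm":
        if mat.shape[0] != 4:
            raise ValueError(f"{path}: JASPAR pfm needs exactly 4 rows (A,C,G,T)")
        counts = mat
    elif format == "hocomoco_pcm":
        if mat.shape[1] != 4:
            raise ValueError(f"{path}: HOCOMOCO pcm needs 4 columns (A,C,G,T)")
        counts = mat.T
    else:
        raise ValueError(f"unknown PWM format: {format!r}")
    return pwm_from_counts(counts, motif_id, tf_name, pseudocount)


def _lattice(pwm: PWM) -> np.ndarray:
    return np.rint(pwm.log_odds / SCORE_BIN_BITS).astype(np.int64)


def score_distribution(pwm: PWM) -> tuple[np.ndarray, int]:
    """Exact null pmf of lattice window scores for a background L-mer.

    Returns (pmf, offset): pmf[k] = P(lattice score == k + offset).
    The result is cached on the PWM instance.
    """
    cached = getattr(pwm, "_score_dist", None)
    if cached is not None:
        return cached
    lat = _lattice(pwm)
    lo = int(lat.min(axis=0).sum())
    hi = int(lat.max(axis=0).sum())
    pmf = np.zeros(hi - lo + 1)
    # DP column by column; running support is [cur_lo, cur_hi]
    cur = np.array([1.0])
    cur_lo = 0
    for j in range(pwm.length):
        col = lat[:, j]
        new_lo = cur_lo + int(col.min())
        new_hi = cur_lo + len(cur) - 1 + int(col.max())
        new = np.zeros(new_hi - new_lo + 1)
        for b in range(4):
            shift = cur_lo + int(col[b]) - new_lo
            new[shift : shift + len(cur)] += pwm.background[b] * cur
        cur, cur_lo = new, new_lo
    pmf[cur_lo - lo : cur_lo - lo + len(cur)] = cur
    pwm._score_dist = (pmf, lo)  # type: ignore[attr-defined]
    return pmf, lo


def _tail_table(pwm: PWM) -> tuple[np.ndarray, int]:
    """Cached upper-tail CDF over the lattice: tail[i] = P(score >= offset + i)."""
    cached = getattr(pwm, "_score_tail", None)
    if cached is not None:
        return cached
    pmf, offset = score_distribution(pwm)
    tail = pmf[::-1].cumsum()[::-1]
    pwm._score_tail = (tail, offset)  # type: ignore[attr-defined]
    return tail, offset


def exact_score_pvalue(pwm: PWM, score: float) -> float:
    """P(random background L-mer scores >= score), exact on the score lattice.

    Monotone non-increasing in score; 0 strictly above the maximum
    attainable score (the maximum itself maps to the top lattice cell).
    """
    if score > pwm.max_score + 1e-9:
        return 0.0
    tail, offset = _tail_table(pwm)
    k = min(int(np.rint(score / SCORE_BIN_BITS)), offset + len(tail) - 1)
    if k <= offset:
        return 1.0
    return float(tail[k - offset])


def score_threshold(pwm: PWM, p_threshold: float) -> float:
    """Smallest real score whose exact tail probability is <= p_threshold."""
    tail, offset = _tail_table(pwm)
    ok = np.flatnonzero(tail <= p_threshold)
    if ok.size == 0:
        return np.inf
    return (offset + int(ok[0])) * SCORE_BIN_BITS


def encode_sequence(seq: str) -> np.ndarray:
    """Map ACGTN (uppercase) to 0..4; any other symbol is an error."""
    table = np.full(256, -1, dtype=np.int8)
    for i, b in enumerate("ACGTN"):
        table[ord(b)] = i
    arr = table[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]
    if (arr < 0).any():
        bad = seq[int(np.flatnonzero(arr < 0)[0])]
        raise ValueError(f"sequence contains unsupported symbol {bad!r}")
    return arr.astype(np.int64)


def _window_scores(encoded: np.ndarray, log_odds: np.ndarray) -> np.ndarray:
    L = log_odds.shape[1]
    if len(encoded) < L:
        return np.zeros(0)
    lo5 = np.vstack([log_odds, np.zeros(L)])  # N scores as background (log-odds 0)
    windows = np.lib.stride_tricks.sliding_window_view(encoded, L)
    return lo5[windows, np.arange(L)].sum(axis=1)


def scan_motifs(
    sequences: dict[str, str],
    pwms: list[PWM],
    p_threshold: float = DEFAULT_P_THRESHOLD,
) -> list[MotifHit]:
    """Scan uppercase ACGTN sequences with each PWM on both strands.

    A hit is any window whose exact tail probability is <= p_threshold;
    overlapping hits of one motif on one strand are all reported. Minus-
    strand hits are reported at the forward-strand window coordinates.
    """
    hits: list[MotifHit] = []
    for pwm in pwms:
        tail, offset = _tail_table(pwm)
        passing = np.flatnonzero(tail <= p_threshold)
        if passing.size == 0:
            continue
        kmin = offset + int(passing[0])  # lattice threshold; matches exact_score_pvalue

        def pval(k: int) -> float:
            if k > offset + len(tail) - 1:
                return 0.0
            if k <= offset:
                return 1.0
            return float(tail[k - offset])

        for name in sorted(sequences):
            enc = encode_sequence(sequences[name].upper())
            for strand, lo in (("+", pwm.log_odds), ("-", pwm.reverse_complement_log_odds())):
                scores = _window_scores(enc, lo)
                lattice_scores = np.rint(scores / SCORE_BIN_BITS).astype(np.int64)
                for i in np.flatnonzero(lattice_scores >= kmin):
                    hits.append(
                        MotifHit(
                            interval=GenomicInterval(name, int(i), int(i) + pwm.length),
                            motif_id=pwm.motif_id,
                            strand=strand,
                            score=float(scores[i]),
                            p_at_score=pval(int(lattice_scores[i])),
                        )
                    )
    hits.sort(key=lambda h: (h.motif_id, h.interval.chrom, h.interval.start, h.strand))
    return hits


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def motif_region_preference(
    annotated_peaks: list,
    enriched_in: dict[str, str],
    hits: list[MotifHit],
    expr: pd.DataFrame,
    comparison: tuple[str, str],
    motif_tf_map: dict[str, str],
    q_threshold: float = 0.05,
) -> tuple[pd.DataFrame, list[str]]:
    """Fisher-exact motif preference per (motif, cell, genome category).

    ``annotated_peaks`` covers every consensus peak (``AnnotatedPeak`` items);
    a peak's key is ``chrom:start-end`` and hit sequence names must use the
    same keys. ``enriched_in`` maps keys of significantly differential peaks
    to their enriched cell. For each motif and cell of the comparison
    (skipping motifs whose TF has RPKM <= 0 in that cell, or no TF mapping),
    each category is tested as: peaks of that category enriched in the cell
    and containing the motif, against all other consensus peaks. The
    ``present`` flag requires BH q <= q_threshold and odds ratio > 1.

    Returns (table, excluded-motif log).
    """
    peak_key = lambda ap: f"{ap.interval.chrom}:{ap.interval.start}-{ap.interval.end}"
    keys = [peak_key(ap) for ap in annotated_peaks]
    categories = {k: ap.category for k, ap in zip(keys, annotated_peaks)}
    motif_bearing: dict[str, set[str]] = {}
    for h in hits:
        motif_bearing.setdefault(h.motif_id, set()).add(h.interval.chrom)

    rows = []
    excluded: list[str] = []
    all_categories = sorted({ap.category for ap in annotated_peaks})
    for motif_id in sorted(motif_bearing):
        tf = motif_tf_map.get(motif_id)
        if tf is None or tf not in expr.index:
            excluded.append(f"{motif_id}: no TF-to-gene mapping")
            continue
        bearing = motif_bearing[motif_id]
        for cell in comparison:
            if float(expr.at[tf, cell]) <= 0:
                excluded.append(f"{motif_id}: {tf} not expressed in {cell} (RPKM <= 0)")
                continue
            for cat in all_categories:
                in_group = [k for k in keys if categories[k] == cat and enriched_in.get(k) == cell]
                out_group = [k for k in keys if not (categories[k] == cat and enriched_in.get(k) == cell)]
                a = sum(k in bearing for k in in_group)
                b = len(in_group) - a
                c = sum(k in bearing for k in out_group)
                d = len(out_group) - c
                odds, p = stats.fisher_exact([[a, b], [c, d]], alternative="two-sided")
                rows.append(
                    {
                        "motif_id": motif_id,
                        "tf": tf,
                        "cell": cell,
                        "category": cat,
                        "n_with_motif": a,
                        "n_group": len(in_group),
                        "odds_ratio": odds,
                        "p_value": p,
                    }
                )
    table = pd.DataFrame(rows)
    if len(table):
        table["q_value"] = multipletests(table["p_value"], method="fdr_bh")[1]
        table["present"] = (table["q_value"] <= q_threshold) & (table["odds_ratio"] > 1)
    return table, excluded


def validate_vs_chip(
    hits: RegionSet,
    chip: RegionSet,
    universe: RegionSet,
    motif_id: str = "",
    restrict_chip_to_universe: bool = False,
) -> ValidationRates:
    """Overlap-based validation of genome-mapped motif hits against ChIP peaks.

    tp_pct: % of ChIP peaks (optionally intersected with the open-chromatin
    universe first) overlapping >= 1 hit; fn_pct = 100 - tp_pct; fp_pct: % of
    universe regions that contain >= 1 hit yet overlap no ChIP peak.
    """
    if len(chip) == 0 or len(universe) == 0:
        raise ValueError("validation rates undefined for empty ChIP or universe sets")
    chip_eval = intersect_any(chip, universe) if restrict_chip_to_universe else chip
    if len(chip_eval) == 0:
        raise ValueError("no ChIP peaks remain after restricting to the universe")
    n_tp = len(intersect_any(chip_eval, hits)) if len(hits) else 0
    tp = 100.0 * n_tp / len(chip_eval)
    with_hit = intersect_any(universe, hits) if len(hits) else RegionSet([])
    n_fp = len(with_hit) - len(intersect_any(with_hit, chip)) if len(with_hit) else 0
    fp = 100.0 * n_fp / len(universe)
    return ValidationRates(
        motif_id=motif_id,
        tp_pct=tp,
        fp_pct=fp,
        fn_pct=100.0 - tp,
        n_chip=len(chip_eval),
        n_universe=len(universe),
    )
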