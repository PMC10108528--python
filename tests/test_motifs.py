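"""Motif machinery: PWM parsing, exact p-values vs exhaustive enumeration,
scanning vs brute force, preference testing, and ChIP validation."""

import itertools

import numpy as np
import pandas as pd
import pytest

from isletkit.annotate import AnnotatedPeak
from isletkit.intervals import GenomicInterval, RegionSet
from isletkit.motifs import (
    SCORE_BIN_BITS,
    MotifHit,
    exact_score_pvalue,
    pwm_from_counts,
    read_pwm,
    reverse_complement,
    motif_region_preference,
    scan_motifs,
    score_distribution,
    validate_vs_chip,
)


def random_pwm(rng, L, motif_id="M_RAND"):
    counts = rng.integers(0, 40, size=(4, L)).astype(float)
    return pwm_from_counts(counts, motif_id)


class TestReadPwm:
    def test_uniform_counts_give_zero_log_odds(self, tmp_path):
        p = tmp_path / "u.pfm"
        p.write_text(">M_U\n" + "\n".join(f"{b} 10 10 10 10 10" for b in "ACGT"))
        pwm = read_pwm(p)
        assert np.allclose(pwm.log_odds, 0.0)

    def test_dominant_base_limit(self, tmp_path):
        p = tmp_path / "a.pfm"
        rows = {b: ("1000 " * 5).strip() if b == "A" else ("0 " * 5).strip() for b in "ACGT"}
        p.write_text(">M_A\n" + "\n".join(f"{b} [ {rows[b]} ]" for b in "ACGT"))
        pwm = read_pwm(p)
        assert np.all(pwm.log_odds[0] > 1.9)
        assert np.all(pwm.log_odds[1:] < -5)

    def test_column_sums_normalized(self, tmp_path):
        rng = np.random.default_rng(2)
        p = tmp_path / "r.pfm"
        counts = rng.integers(0, 50, size=(4, 8))
        p.write_text(">M_R\n" + "\n".join(" ".join(str(v) for v in row) for row in counts))
        pwm = read_pwm(p)
        assert np.allclose(pwm.matrix.sum(axis=0), 1.0, atol=1e-9)

    def test_hocomoco_pcm_orientation(self, tmp_path):
        p = tmp_path / "h.pcm"
        p.write_text(">M_H\n90 0 5 5\n0 90 5 5\n5 5 90 0\n5 5 0 90\n")
        pwm = read_pwm(p, format="hocomoco_pcm")
        assert pwm.length == 4
        assert pwm.consensus == "ACGT"

    def test_ragged_matrix_rejected(self, tmp_path):
        p = tmp_path / "bad.pfm"
        p.write_text(">M_B\n1 2 3\n1 2\n1 2 3\n1 2 3\n")
        with pytest.raises(ValueError, match="ragged"):
            read_pwm(p)

    def test_zero_column_rescued_by_pseudocount(self, tmp_path):
        p = tmp_path / "z.pfm"
        p.write_text(">M_Z\n0 10 10 10\n0 10 10 10\n0 10 10 10\n0 10 10 10\n")
        pwm = read_pwm(p)
        assert np.isfinite(pwm.log_odds).all()


def enumerate_lattice_tail(pwm, k):
    """Brute-force P(lattice word score >= k) over all 4^L words.

    Mirrors the DP discretization (per-column rounding) so the convolution
    itself can be checked for exact equality.
    """
    lat = np.rint(pwm.log_odds / SCORE_BIN_BITS).astype(int)
    total = 0.0
    for word in itertools.product(range(4), repeat=pwm.length):
        if sum(lat[b, j] for j, b in enumerate(word)) >= k:
            total += float(np.prod([pwm.background[b] for b in word]))
    return total


def enumerate_true_tail(pwm, score):
    """Brute-force P(true word score >= score) over all 4^L words."""
    total = 0.0
    for word in itertools.product(range(4), repeat=pwm.length):
        s = sum(pwm.log_odds[b, j] for j, b in enumerate(word))
        if s >= score:
            total += float(np.prod([pwm.background[b] for b in word]))
    return total


class TestExactPvalue:
    def test_boundary_scores(self):
        rng = np.random.default_rng(3)
        pwm = random_pwm(rng, 6)
        assert exact_score_pvalue(pwm, -1e9) == 1.0
        assert exact_score_pvalue(pwm, pwm.max_score + 1.0) == 0.0

    def test_max_score_tail_equals_product_of_max_base_probs(self):
        # strongly peaked motif: the only word at the max is the consensus
        counts = np.full((4, 5), 1.0)
        for j in range(5):
            counts[j % 4, j] = 97.0
        pwm = pwm_from_counts(counts, "M_PEAK")
        p = exact_score_pvalue(pwm, pwm.max_score)
        assert p == pytest.approx(0.25 ** 5, rel=1e-9)
        assert p == pytest.approx(enumerate_true_tail(pwm, pwm.max_score), rel=1e-9)

    @pytest.mark.parametrize("L", [5, 6])
    def test_dp_convolution_equals_lattice_enumeration(self, L):
        rng = np.random.default_rng(40 + L)
        pwm = random_pwm(rng, L)
        pmf, offset = score_distribution(pwm)
        for k in np.linspace(offset, offset + len(pmf) - 1, 9).astype(int):
            dp_tail = float(pmf[k - offset :].sum())
            assert dp_tail == pytest.approx(enumerate_lattice_tail(pwm, int(k)), abs=1e-12)

    @pytest.mark.parametrize("L", [5, 6])
    def test_within_lattice_tolerance_of_true_enumeration(self, L):
        # per-column rounding shifts any word by at most L/2 bins, so the DP
        # tail is sandwiched by true-score tails at score -/+ that slack
        rng = np.random.default_rng(40 + L)
        pwm = random_pwm(rng, L)
        slack = (L + 1) * SCORE_BIN_BITS / 2
        lo, hi = float(pwm.log_odds.min(axis=0).sum()), pwm.max_score
        for score in np.linspace(lo + slack, hi - slack, 7):
            dp = exact_score_pvalue(pwm, float(score))
            assert enumerate_true_tail(pwm, float(score) + slack) - 1e-12 <= dp
            assert dp <= enumerate_true_tail(pwm, float(score) - slack) + 1e-12

    def test_monotone_non_increasing(self):
        rng = np.random.default_rng(9)
        pwm = random_pwm(rng, 8)
        scores = np.linspace(pwm.log_odds.min(axis=0).sum(), pwm.max_score, 50)
        pvals = [exact_score_pvalue(pwm, float(s)) for s in scores]
        assert all(a >= b for a, b in zip(pvals, pvals[1:]))

    def test_distribution_sums_to_one(self):
        rng = np.random.default_rng(11)
        pwm = random_pwm(rng, 7)
        pmf, _ = score_distribution(pwm)
        assert pmf.sum() == pytest.approx(1.0, abs=1e-9)


def brute_force_scan(sequences, pwm, p_threshold):
    """Score every window on both strands; keep windows with exact p <= threshold."""
    found = []
    lo5 = np.vstack([pwm.log_odds, np.zeros(pwm.length)])
    lo5_rc = np.vstack([pwm.reverse_complement_log_odds(), np.zeros(pwm.length)])
    code = {b: i for i, b in enumerate("ACGTN")}
    for name in sorted(sequences):
        seq = sequences[name].upper()
        for strand, lo in (("+", lo5), ("-", lo5_rc)):
            for i in range(len(seq) - pwm.length + 1):
                s = sum(lo[code[seq[i + j]], j] for j in range(pwm.length))
                if exact_score_pvalue(pwm, s) <= p_threshold:
                    found.append((name, i, strand))
    return sorted(found)


class TestScan:
    def test_planted_consensus_recovered(self):
        rng = np.random.default_rng(6)
        counts = np.full((4, 8), 1.0)
        cons = "ACGTACGT"
        for j, b in enumerate(cons):
            counts["ACGT".index(b), j] = 97.0
        pwm = pwm_from_counts(counts, "M_C")
        bg = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 120)])
        seq = bg[:40] + cons + bg[48:]
        hits = scan_motifs({"s1": seq}, [pwm], p_threshold=1e-4)
        assert any(h.interval.start == 40 and h.strand == "+" for h in hits)

    def test_reverse_complement_symmetry(self):
        rng = np.random.default_rng(14)
        pwm = random_pwm(rng, 7)
        seq = "".join(np.array(list("ACGT"))[rng.integers(0, 4, 150)])
        fwd = scan_motifs({"s": seq}, [pwm], p_threshold=5e-3)
        rev = scan_motifs({"s": reverse_complement(seq)}, [pwm], p_threshold=5e-3)
        flipped = sorted(
            (len(seq) - h.interval.end, {"+": "-", "-": "+"}[h.strand], round(h.score, 6)) for h in rev
        )
        original = sorted((h.interval.start, h.strand, round(h.score, 6)) for h in fwd)
        assert original == flipped

    def test_short_sequence_yields_no_windows(self):
        rng = np.random.default_rng(1)
        pwm = random_pwm(rng, 8)
        assert scan_motifs({"s": "ACGT"}, [pwm]) == []

    def test_n_bases_score_as_background(self):
        counts = np.full((4, 4), 1.0)
        counts[0] = 97.0  # AAAA consensus
        pwm = pwm_from_counts(counts, "M_N")
        hits_with_n = scan_motifs({"s": "AANA"}, [pwm], p_threshold=1.0)
        [h] = [h for h in hits_with_n if h.strand == "+"]
        expected = pwm.log_odds[0, 0] + pwm.log_odds[0, 1] + 0.0 + pwm.log_odds[0, 3]
        assert h.score == pytest.approx(expected)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(77)
        pwm = random_pwm(rng, 9)
        seqs = {
            f"s{i}": "".join(np.array(list("ACGT"))[rng.integers(0, 4, 200)]) for i in range(30)
        }
        hits = scan_motifs(seqs, [pwm], p_threshold=2e-3)
        got = sorted((h.interval.chrom, h.interval.start, h.strand) for h in hits)
        assert got == brute_force_scan(seqs, pwm, 2e-3)


def _annotated(key_coords):
    out = []
    for (chrom, start, end), cat in key_coords:
        out.append(AnnotatedPeak(GenomicInterval(chrom, start, end), cat, "g", 0.0))
    return out


class TestRegionPreference:
    def _scenario(self):
        peaks = []
        # 10 promoter peaks enriched in beta, 30 background distal peaks
        for i in range(10):
            peaks.append((("chr1", 1_000 * i, 1_000 * i + 200), "promoter_proximal"))
        for i in range(30):
            peaks.append((("chr2", 1_000 * i, 1_000 * i + 200), "distal_intergenic"))
        annotated = _annotated(peaks)
        enriched = {f"chr1:{1_000 * i}-{1_000 * i + 200}": "beta" for i in range(10)}
        return annotated, enriched

    def _hits(self, keys):
        return [
            MotifHit(GenomicInterval(k, 0, 8), "M_X", "+", 10.0, 1e-5) for k in keys
        ]

    def test_planted_promoter_preference_flagged(self):
        annotated, enriched = self._scenario()
        hits = self._hits([f"chr1:{1_000 * i}-{1_000 * i + 200}" for i in range(10)])
        expr = pd.DataFrame({"alpha": [1.0], "beta": [5.0]}, index=["TFX"])
        table, excluded = motif_region_preference(
            annotated, enriched, hits, expr, ("alpha", "beta"), {"M_X": "TFX"}
        )
        flagged = table[table["present"]]
        assert set(zip(flagged["cell"], flagged["category"])) == {("beta", "promoter_proximal")}
        assert excluded == []

    def test_unexpressed_tf_excluded_from_that_cell(self):
        annotated, enriched = self._scenario()
        hits = self._hits([f"chr1:{1_000 * i}-{1_000 * i + 200}" for i in range(10)])
        expr = pd.DataFrame({"alpha": [0.0], "beta": [5.0]}, index=["TFX"])
        table, excluded = motif_region_preference(
            annotated, enriched, hits, expr, ("alpha", "beta"), {"M_X": "TFX"}
        )
        assert "alpha" not in set(table["cell"])
        assert any("not expressed in alpha" in e for e in excluded)

    def test_unmapped_motif_logged(self):
        annotated, enriched = self._scenario()
        hits = self._hits(["chr1:0-200"])
        expr = pd.DataFrame({"alpha": [1.0], "beta": [1.0]}, index=["TFY"])
        table, excluded = motif_region_preference(
            annotated, enriched, hits, expr, ("alpha", "beta"), {}
        )
        assert len(table) == 0
        assert any("no TF-to-gene mapping" in e for e in excluded)

    def test_uniform_planting_not_flagged(self):
        annotated, enriched = self._scenario()
        keys = [f"{ap.interval.chrom}:{ap.interval.start}-{ap.interval.end}" for ap in annotated]
        hits = self._hits(keys)  # motif everywhere: no signal
        expr = pd.DataFrame({"alpha": [1.0], "beta": [5.0]}, index=["TFX"])
        table, _ = motif_region_preference(
            annotated, enriched, hits, expr, ("alpha", "beta"), {"M_X": "TFX"}
        )
        assert not table["present"].any()


class TestValidateVsChip:
    def _rs(self, coords):
        return RegionSet([GenomicInterval(c, s, e) for c, s, e in coords])

    def test_perfect_hits(self):
        chip = self._rs([("chr1", 100 * i, 100 * i + 50) for i in range(10)])
        rates = validate_vs_chip(chip, chip, chip)
        assert rates.tp_pct == 100.0 and rates.fn_pct == 0.0 and rates.fp_pct == 0.0

    def test_no_hits(self):
        chip = self._rs([("chr1", 0, 50)])
        universe = self._rs([("chr1", 0, 50), ("chr1", 100, 150)])
        rates = validate_vs_chip(RegionSet([]), chip, universe)
        assert rates.tp_pct == 0.0 and rates.fn_pct == 100.0 and rates.fp_pct == 0.0

    def test_hand_enumerated_toy(self):
        universe = self._rs([("chr1", 100 * i, 100 * i + 60) for i in range(30)])
        chip = self._rs([("chr1", 100 * i, 100 * i + 60) for i in range(20)])
        # hits on universe regions 0..11: 12 hit-bearing; 12 of 20 chip hit, 0 fp
        hits = self._rs([("chr1", 100 * i + 10, 100 * i + 20) for i in range(12)])
        rates = validate_vs_chip(hits, chip, universe)
        assert rates.tp_pct == pytest.approx(60.0)
        assert rates.fn_pct == pytest.approx(40.0)
        assert rates.fp_pct == pytest.approx(0.0)
        # shift hits onto non-chip universe regions 20..25 -> all false positives
        hits_fp = self._rs([("chr1", 100 * i + 10, 100 * i + 20) for i in range(20, 26)])
        rates_fp = validate_vs_chip(hits_fp, chip, universe)
        assert rates_fp.tp_pct == 0.0
        assert rates_fp.fp_pct == pytest.approx(100.0 * 6 / 30)

    def test_tp_plus_fn_is_identity(self):
        rng = np.random.default_rng(5)
        universe = self._rs([("chr1", int(s), int(s) + 80) for s in rng.integers(0, 50_000, 40)])
        chip = self._rs([("chr1", int(s), int(s) + 80) for s in rng.integers(0, 50_000, 25)])
        hits = self._rs([("chr1", int(s), int(s) + 10) for s in rng.integers(0, 50_000, 60)])
        rates = validate_vs_chip(hits, chip, universe)
        assert rates.tp_pct + rates.fn_pct == pytest.approx(100.0)

    def test_empty_chip_rejected(self):
        u = self._rs([("chr1", 0, 10)])
        with pytest.raises(ValueError):
            validate_vs_chip(u, RegionSet([]), u)
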