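"""Enhancer chain: conjunction calling vs a bitmap oracle, filters, state
rules, specificity partition, overlap stats, and the permutation test."""

import numpy as np
import pytest

from isletkit.enhancers import (
    EnhancerCall,
    call_putative,
    classify_state,
    filter_accessible,
    filter_catalog,
    overlap_stats,
    permutation_enrichment,
    specificity_partition,
)
from isletkit.intervals import GenomicInterval, RegionSet

from conftest import random_region_set


def _rs(coords, **meta):
    return RegionSet([GenomicInterval(c, s, e) for c, s, e in coords], meta=meta)


class TestCallPutative:
    def test_requires_both_marks_and_tf(self):
        h27 = _rs([("chr1", 100, 700)])
        h1 = _rs([("chr1", 400, 1_000)])
        tf = {"Pdx1": _rs([("chr1", 450, 600)])}
        calls = call_putative(h27, h1, tf)
        assert [(c.region.start, c.region.end) for c in calls] == [(400, 700)]
        assert calls[0].cobinding_count == 1 and calls[0].tf_list == ("Pdx1",)

    def test_single_mark_region_not_emitted(self):
        h27 = _rs([("chr1", 100, 700)])
        h1 = _rs([("chr2", 100, 700)])
        tf = {"Pdx1": _rs([("chr1", 100, 700), ("chr2", 100, 700)])}
        assert call_putative(h27, h1, tf) == []

    def test_candidate_without_tf_dropped(self):
        h27 = _rs([("chr1", 100, 700)])
        h1 = _rs([("chr1", 100, 700)])
        tf = {"Pdx1": _rs([("chr2", 0, 100)])}
        assert call_putative(h27, h1, tf) == []

    def test_track_distinct_counting(self):
        h27 = _rs([("chr1", 0, 1_000)])
        h1 = _rs([("chr1", 0, 1_000)])
        tfs = {f"tf{i}": _rs([("chr1", 100 * i, 100 * i + 80)]) for i in range(8)}
        [call] = call_putative(h27, h1, tfs)
        assert call.cobinding_count == 8

    def test_per_peak_counting_mode(self):
        h27 = _rs([("chr1", 0, 1_000)])
        h1 = _rs([("chr1", 0, 1_000)])
        tfs = {"tfA": _rs([("chr1", 100, 180), ("chr1", 300, 380), ("chr1", 500, 580)])}
        [track_call] = call_putative(h27, h1, tfs, count_mode="track")
        [peak_call] = call_putative(h27, h1, tfs, count_mode="peak")
        assert track_call.cobinding_count == 1
        assert peak_call.cobinding_count == 3

    def test_zero_tf_tracks_rejected(self):
        h = _rs([("chr1", 0, 100)])
        with pytest.raises(ValueError):
            call_putative(h, h, {})

    def test_matches_bitmap_conjunction_oracle(self):
        rng = np.random.default_rng(55)
        for _ in range(8):
            h27 = random_region_set(rng, 40, chroms=("chr1",), max_pos=100_000, max_len=1_500)
            h1 = random_region_set(rng, 40, chroms=("chr1",), max_pos=100_000, max_len=1_500)
            tf = {"t": random_region_set(rng, 30, chroms=("chr1",), max_pos=100_000, max_len=500)}
            calls = call_putative(h27, h1, tf)
            bm27 = np.zeros(110_000, dtype=bool)
            bm1 = np.zeros(110_000, dtype=bool)
            bmt = np.zeros(110_000, dtype=bool)
            for iv in h27:
                bm27[iv.start : iv.end] = True
            for iv in h1:
                bm1[iv.start : iv.end] = True
            for iv in tf["t"]:
                bmt[iv.start : iv.end] = True
            conj = bm27 & bm1
            pieces = []
            i = 0
            while i < len(conj):
                if conj[i]:
                    j = i
                    while j < len(conj) and conj[j]:
                        j += 1
                    pieces.append((i, j))
                    i = j
                else:
                    i += 1
            expected = [(s, e) for s, e in pieces if bmt[s:e].any()]
            assert [(c.region.start, c.region.end) for c in sorted(calls, key=lambda c: c.region.start)] == expected


def _call(chrom, start, end, cobind=1):
    return EnhancerCall(
        region=GenomicInterval(chrom, start, end), cobinding_count=cobind, tf_list=("t",) * cobind
    )


class TestFilters:
    def test_accessibility_annotation_and_retention(self):
        calls = [_call("chr1", 0, 600), _call("chr1", 1_000, 1_600)]
        atac = {
            "beta": _rs([("chr1", 100, 300)]),
            "alpha": _rs([("chr2", 0, 100)]),
            "delta": _rs([("chr2", 0, 100)]),
        }
        annotated, active = filter_accessible(calls, atac)
        assert annotated[0].accessible_in == frozenset({"beta"})
        assert annotated[0].specificity == "unique_beta"
        assert annotated[1].accessible_in == frozenset()
        assert [c.region.start for c in active] == [0]

    def test_unknown_cell_key_rejected(self):
        with pytest.raises(ValueError, match="unknown cell"):
            filter_accessible([_call("chr1", 0, 600)], {"gamma": _rs([("chr1", 0, 10)])})

    def test_empty_catalog_gives_empty_conservative(self):
        calls = [_call("chr1", 0, 600)]
        assert filter_catalog(calls, RegionSet([])) == []
        assert calls[0].catalog_supported is False

    def test_catalog_equal_to_calls_is_identity(self):
        calls = [_call("chr1", 0, 600), _call("chr2", 0, 600)]
        catalog = _rs([("chr1", 0, 600), ("chr2", 0, 600)])
        assert filter_catalog(calls, catalog) == calls


class TestClassifyState:
    H27 = _rs([("chr1", 0, 600)])
    H1 = _rs([("chr1", 0, 600)])
    H3 = _rs([("chr1", 0, 600)])
    EMPTY = RegionSet([])
    REGION = GenomicInterval("chr1", 100, 500)

    def test_h3k4me1_only_is_poised(self):
        assert classify_state(self.REGION, self.EMPTY, self.H1, self.EMPTY) == "poised"

    def test_both_activating_marks_is_active(self):
        assert classify_state(self.REGION, self.H27, self.H1, self.EMPTY) == "active"

    def test_h3k4me3_takes_precedence(self):
        assert classify_state(self.REGION, self.H27, self.H1, self.H3) == "active_promoter"

    def test_h3k27ac_alone_is_none(self):
        assert classify_state(self.REGION, self.H27, self.EMPTY, self.EMPTY) == "none"


class TestSpecificityPartition:
    def test_counts_percentages_and_inaccessible_base(self):
        cells_sets = (
            [frozenset({"alpha", "beta", "delta"})] * 20
            + [frozenset({"beta"})] * 10
            + [frozenset({"alpha"})] * 5
            + [frozenset({"delta"})] * 5
            + [frozenset({"alpha", "beta"})] * 10
            + [frozenset()] * 3
        )
        calls = []
        for i, s in enumerate(cells_sets):
            c = _call("chr1", 1_000 * i, 1_000 * i + 600)
            c.accessible_in = s
            from isletkit.enhancers import specificity_class

            c.specificity = specificity_class(s)
            calls.append(c)
        part = specificity_partition(calls)
        assert part.at["common_all", "n"] == 20
        assert part.at["unique_beta", "n"] == 10
        assert part.at["pair_ab", "n"] == 10
        assert part.at["inaccessible", "n"] == 3
        accessible = part.loc[part.index != "inaccessible", "pct"]
        assert accessible.sum() == pytest.approx(100.0)
        assert part.at["common_all", "pct"] == pytest.approx(100.0 * 20 / 50)


class TestOverlapStats:
    def test_full_cover_and_disjoint(self):
        open_c = _rs([("chr1", 0, 100), ("chr1", 200, 300)])
        chip_cover = _rs([("chr1", 0, 300)])
        assert overlap_stats(open_c, chip_cover)[0] == 100.0
        disjoint = _rs([("chr2", 0, 100)])
        assert overlap_stats(open_c, disjoint) == (0.0, 0.0)

    def test_hand_enumerated_toy(self):
        open_c = _rs([("chr1", 1_000 * i, 1_000 * i + 100) for i in range(10)])
        chip = _rs(
            [("chr1", 1_000 * i + 50, 1_000 * i + 150) for i in range(4)]
            + [("chr2", 1_000 * i, 1_000 * i + 100) for i in range(4)]
        )
        pct_open, pct_chip = overlap_stats(open_c, chip)
        assert pct_open == pytest.approx(40.0)
        assert pct_chip == pytest.approx(50.0)

    def test_empty_sets_rejected(self):
        some = _rs([("chr1", 0, 10)])
        with pytest.raises(ValueError):
            overlap_stats(RegionSet([]), some)


class TestPermutation:
    SIZES = {"chr1": 200_000}

    def test_saturating_target_gives_p_one(self):
        a = _rs([("chr1", 1_000 * i, 1_000 * i + 100) for i in range(10)])
        b = _rs([("chr1", 0, 200_000)])
        res = permutation_enrichment(a, b, self.SIZES, n_perm=50, seed=1)
        assert res.observed_overlap == 10
        assert res.p_empirical == 1.0

    def test_colocated_tracks_attain_minimum_p(self):
        a = _rs([("chr1", 5_000 * i, 5_000 * i + 200) for i in range(20)])
        res = permutation_enrichment(a, a, self.SIZES, n_perm=99, seed=13)
        assert res.p_empirical == pytest.approx(1.0 / 100.0)
        assert res.z > 3

    def test_p_bounds_and_determinism(self):
        rng = np.random.default_rng(8)
        a = random_region_set(rng, 15, chroms=("chr1",), max_pos=190_000, max_len=300)
        b = random_region_set(rng, 15, chroms=("chr1",), max_pos=190_000, max_len=300)
        r1 = permutation_enrichment(a, b, self.SIZES, n_perm=40, seed=3)
        r2 = permutation_enrichment(a, b, self.SIZES, n_perm=40, seed=3)
        assert r1 == r2
        assert 1.0 / 41.0 <= r1.p_empirical <= 1.0

    def test_region_longer_than_chromosome_rejected(self):
        a = _rs([("chr1", 0, 300_000)])
        with pytest.raises(ValueError):
            permutation_enrichment(a, a, self.SIZES, n_perm=5, seed=0)


class TestWorldRecovery:
    def test_chain_recovers_planted_enhancers_exactly(self, pipeline_results, default_world):
        """Putative -> active -> conservative must equal the manifest with no decoys."""
        w = default_world
        en = pipeline_results["enhancers"]
        putative, active, conservative = en["putative"], en["active"], en["conservative"]

        def keys(calls):
            return {(c.region.chrom, c.region.start, c.region.end) for c in calls}

        planted_active = {
            (e["chrom"], e["start"], e["end"]) for e in w.truth.enhancers if e["state"] == "active"
        }
        planted_accessible = {
            (e["chrom"], e["start"], e["end"])
            for e in w.truth.enhancers
            if e["state"] == "active" and e["cells"]
        }
        planted_catalog = {
            (e["chrom"], e["start"], e["end"]) for e in w.truth.enhancers if e["catalog"]
        }
        assert keys(putative) == planted_active       # all planted found, zero decoys
        assert keys(active) == planted_accessible
        assert keys(conservative) == planted_catalog
        assert keys(conservative) <= keys(active) <= keys(putative)

        by_key = {(e["chrom"], e["start"], e["end"]): e for e in w.truth.enhancers}
        for c in putative:
            e = by_key[(c.region.chrom, c.region.start, c.region.end)]
            assert c.cobinding_count == e["cobinding"]
            assert set(c.tf_list) == set(e["tfs"])
        for c in active:
            e = by_key[(c.region.chrom, c.region.start, c.region.end)]
            assert c.accessible_in == frozenset(e["cells"])
            assert c.specificity == e["class"]

    def test_planted_states_classified_by_mark_rules(self, default_world):
        from isletkit.intervals import read_regions

        w = default_world
        h27 = read_regions(w.paths["histone"]["H3K27ac"])
        h1 = read_regions(w.paths["histone"]["H3K4me1"])
        h3 = read_regions(w.paths["histone"]["H3K4me3"])
        for e in w.truth.enhancers:
            region = GenomicInterval(e["chrom"], e["start"], e["end"])
            assert classify_state(region, h27, h1, h3) == e["state"], e
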