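"""Interval engine: window construction, filtering, merging, shuffling and
nearest distances, checked against per-base brute-force oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats as sps

from conftest import coverage_mask, random_intervals
from teaccess.intervals import (
    GenomicInterval,
    TEAnnotation,
    TSSRecord,
    intersect_te_trr,
    make_trr,
    merge_intervals,
    nearest_distance,
    shuffle_regions,
)

GENOME = {"chr1": 100_000, "chr2": 100_000}


def te(chrom, start, end, family="MIR", sw=250, name="te"):
    cls = {"MIR": "SINE", "Alu": "SINE", "L1": "LINE"}[family]
    return TEAnnotation(GenomicInterval(chrom, start, end, name=name), cls,
                        family, sw)


class TestMakeTrr:
    def test_flank_window(self):
        trrs = make_trr([TSSRecord("g", "chr1", 50_000, "+")], 10_000, GENOME)
        assert (trrs[0].start, trrs[0].end) == (40_000, 60_000)

    def test_boundary_clipping(self):
        trrs = make_trr([TSSRecord("g", "chr1", 4_000, "+")], 10_000, GENOME)
        assert (trrs[0].start, trrs[0].end) == (0, 14_000)

    def test_merge_unions_overlapping_windows(self):
        tss = [TSSRecord("a", "chr1", 50_000, "+"),
               TSSRecord("b", "chr1", 55_000, "+")]
        trrs = make_trr(tss, 10_000, GENOME, merge=True)
        assert [(t.start, t.end) for t in trrs] == [(40_000, 65_000)]
        unmerged = make_trr(tss, 10_000, GENOME, merge=False)
        assert [t.name for t in unmerged] == ["a", "b"]

    def test_errors(self):
        with pytest.raises(KeyError):
            make_trr([TSSRecord("g", "chrX", 10, "+")], 1_000, GENOME)
        with pytest.raises(ValueError):
            make_trr([TSSRecord("g", "chr1", 10, "+")], 0, GENOME)


class TestIntersectTeTrr:
    TRR = [GenomicInterval("chr1", 40_000, 60_000)]

    def test_retained_when_overlapping(self):
        kept = intersect_te_trr([te("chr1", 41_000, 41_300)], self.TRR)
        assert len(kept) == 1

    def test_low_alignment_score_excluded(self):
        kept = intersect_te_trr([te("chr1", 41_000, 41_300, sw=80)], self.TRR)
        assert kept == []

    def test_single_base_overlap_retained(self):
        kept = intersect_te_trr([te("chr1", 39_900, 40_001)], self.TRR)
        assert len(kept) == 1

    def test_family_filter_and_empty_families_error(self):
        kept = intersect_te_trr([te("chr1", 41_000, 41_300)], self.TRR,
                                allowed_families=frozenset({"Alu"}))
        assert kept == []
        with pytest.raises(ValueError):
            intersect_te_trr([], self.TRR, allowed_families=frozenset())


class TestMerge:
    @pytest.mark.parametrize(
        "spans,expected",
        [
            ([(0, 10), (5, 20)], [(0, 20)]),
            ([(0, 10), (10, 20)], [(0, 20)]),  # book-ended
            ([(0, 5), (8, 9)], [(0, 5), (8, 9)]),
        ],
    )
    def test_examples(self, spans, expected):
        ivs = [GenomicInterval("chr1", s, e) for s, e in spans]
        assert [(m.start, m.end) for m in merge_intervals(ivs)] == expected

    @settings(derandomize=True, max_examples=60, deadline=None)
    @given(st.lists(st.tuples(st.integers(0, 500), st.integers(1, 50)),
                    min_size=1, max_size=30))
    def test_idempotent_and_base_preserving(self, spans):
        ivs = [GenomicInterval("chr1", s, s + l) for s, l in spans]
        merged = merge_intervals(ivs)
        assert merge_intervals(merged) == merged
        # same base set as the per-base oracle
        assert np.array_equal(coverage_mask(merged, 600),
                              coverage_mask(ivs, 600))
        # pairwise disjoint and sorted with a gap between neighbours
        for a, b in zip(merged, merged[1:]):
            assert a.end < b.start


class TestNearestDistance:
    def test_overlap_is_zero(self):
        d = nearest_distance([GenomicInterval("chr1", 100, 200)],
                             [GenomicInterval("chr1", 150, 160)])
        assert d["distance"].iloc[0] == 0

    def test_gap(self):
        d = nearest_distance([GenomicInterval("chr1", 100, 200)],
                             [GenomicInterval("chr1", 500, 600)])
        assert d["distance"].iloc[0] == 300

    def test_missing_chromosome(self):
        d = nearest_distance([GenomicInterval("chr2", 100, 200)],
                             [GenomicInterval("chr1", 500, 600)])
        assert np.isnan(d["distance"].iloc[0])
        with pytest.raises(ValueError):
            nearest_distance([GenomicInterval("chr1", 0, 1)], [])

    def test_matches_all_pairs_oracle(self):
        rng = np.random.default_rng(11)
        a = random_intervals(rng, 40, prefix="a")
        b = random_intervals(rng, 40, prefix="b")
        got = nearest_distance(a, b)["distance"].values
        for iv, d in zip(a, got):
            gaps = [
                0 if (x.start < iv.end and x.end > iv.start)
                else max(x.start - iv.end, iv.start - x.end)
                for x in b
            ]
            assert d == min(gaps)


class TestShuffle:
    UNIVERSE = [GenomicInterval("chr1", 0, 10_000)]

    def test_length_multiset_preserved(self):
        q = [GenomicInterval("chr1", 0, 100, name="q1"),
             GenomicInterval("chr1", 500, 750, name="q2")]
        for shuf in shuffle_regions(q, self.UNIVERSE, 20, seed=3):
            assert sorted(len(iv) for iv in shuf) == [100, 250]

    def test_full_inclusion(self):
        q = [GenomicInterval("chr1", 0, 100)]
        for shuf in shuffle_regions(q, self.UNIVERSE, 50,
                                    included_fraction=1.0, seed=5):
            assert shuf[0].start >= 0 and shuf[0].end <= 10_000

    def test_deterministic_under_seed(self):
        q = random_intervals(np.random.default_rng(0), 10, max_pos=9_000)
        a = shuffle_regions(q, self.UNIVERSE, 10, seed=7)
        b = shuffle_regions(q, self.UNIVERSE, 10, seed=7)
        assert a == b

    def test_unplaceable_region_is_named(self):
        q = [GenomicInterval("chr1", 0, 50_000, name="huge")]
        with pytest.raises(ValueError, match="huge"):
            shuffle_regions(q, self.UNIVERSE, 1, included_fraction=1.0, seed=1)

    def test_start_distribution_uniform(self):
        q = [GenomicInterval("chr1", 0, 100)]
        shufs = shuffle_regions(q, self.UNIVERSE, 500,
                                included_fraction=1.0, seed=1)
        starts = np.array([s[0].start for s in shufs])
        counts, _ = np.histogram(starts, bins=10, range=(0, 9_901))
        p = sps.chisquare(counts).pvalue
        assert p > 0.001

    def test_inclusion_fraction_respected(self):
        universe = [GenomicInterval("chr1", 1_000, 2_000),
                    GenomicInterval("chr1", 5_000, 5_600)]
        q = [GenomicInterval("chr1", 0, 400, name="q")]
        mask = coverage_mask(universe, 10_000)
        for shuf in shuffle_regions(q, universe, 200,
                                    included_fraction=0.9, seed=9):
            iv = shuf[0]
            inside = int(mask[iv.start: iv.end].sum())
            assert inside >= int(np.ceil(0.9 * 400))


def test_trr_then_merge_idempotent():
    rng = np.random.default_rng(2)
    tss = [TSSRecord(f"g{i}", "chr1", int(rng.integers(0, 99_000)), "+")
           for i in range(30)]
    trrs = make_trr(tss, 10_000, GENOME, merge=True)
    assert merge_intervals(trrs) == trrs
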