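"""Haploblock construction, merging and block-set arithmetic against
independent brute-force oracles."""

import numpy as np
import pytest
from conftest import (
    bitmap_coverage,
    dec_round,
    oracle_call,
    quadratic_overlaps,
    random_bin_instance,
    records_from_bins,
    sort_median,
)

from haplokit.alignment_io import AlignmentRecord, GenomeInterval
from haplokit.haploblocks import (
    Bin,
    Haploblock,
    HaploblockParams,
    HaploblockSet,
    associate_intervals,
    bin_alignments,
    bin_median,
    block_summary,
    call_haploblocks,
    genome_coverage,
    intersect_haploblock_sets,
    read_haploblocks_tsv,
    write_haploblocks_tsv,
)

BS = 5_000_000


def _rec(start, end, ident=99.0, chrom="chr1S"):
    return AlignmentRecord(chrom, start, end, chrom, start, end, "+", ident)


def _call(bin_lists, chrom_len=None, **kw):
    chrom_len = chrom_len or len(bin_lists) * BS
    params = HaploblockParams(**kw)
    records = records_from_bins(bin_lists, BS)
    return call_haploblocks(records, params, {"chr1S": chrom_len}, "ref", "qry")


class TestBinAssignment:
    def test_midpoint_in_first_bin(self):
        bins = bin_alignments([_rec(0, 20_000)], BS, {"chr1S": 50_000_000})
        assert bins[0].identities == [99.0]

    def test_boundary_spanning_record_goes_to_midpoint_bin(self):
        bins = bin_alignments([_rec(4_999_000, 5_021_000)], BS, {"chr1S": 50_000_000})
        assert bins[0].identities == []
        assert bins[1].identities == [99.0]  # midpoint 5,010,000

    def test_all_bins_present_including_empty(self):
        bins = bin_alignments([], BS, {"chr1S": 12_000_000, "chr2S": 5_000_000})
        assert [(b.chrom, b.index, b.start, b.end) for b in bins] == [
            ("chr1S", 0, 0, 5_000_000),
            ("chr1S", 1, 5_000_000, 10_000_000),
            ("chr1S", 2, 10_000_000, 12_000_000),
            ("chr2S", 0, 0, 5_000_000),
        ]

    def test_midpoint_beyond_length_is_error(self):
        with pytest.raises(ValueError, match="beyond"):
            bin_alignments([_rec(9_000_000, 11_000_000)], BS, {"chr1S": 9_500_000})

    def test_histogram_matches_midpoint_oracle(self, rng):
        chrom_len = 50_000_000
        records = []
        for _ in range(500):
            start = int(rng.integers(0, chrom_len - 100_000))
            records.append(_rec(start, start + int(rng.integers(1000, 100_000))))
        bins = bin_alignments(records, BS, {"chr1S": chrom_len})
        expected = np.zeros(len(bins), dtype=int)
        for r in records:
            expected[((r.ref_start + r.ref_end) // 2) // BS] += 1
        assert [b.n_alignments for b in bins] == expected.tolist()


class TestBinMedian:
    def test_odd_count(self):
        assert bin_median(Bin("c", 0, 0, BS, [99.1, 99.3, 99.5])) == 99.3

    def test_empty_is_null(self):
        assert bin_median(Bin("c", 0, 0, BS, [])) is None

    def test_even_count_mean_of_central_pair(self):
        assert bin_median(Bin("c", 0, 0, BS, [99.0, 99.1, 99.3, 99.8])) == 99.2

    def test_half_up_rounding(self):
        assert bin_median(Bin("c", 0, 0, BS, [99.125]), rounding=2) == 99.13

    def test_matches_sort_oracle(self, rng):
        for _ in range(2000):
            vals = list(rng.uniform(80, 100, size=int(rng.integers(1, 12))))
            b = Bin("c", 0, 0, BS, vals)
            assert bin_median(b, 2) == sort_median(vals, 2)


class TestCallHaploblocks:
    def test_identical_median_merging_with_cutoff(self):
        # medians 99.2, 99.2, 98.7, empty, 99.2 with cutoff 99:
        # bins 0-1 merge, bin 2 fails the cutoff, bin 4 stands alone
        bin_lists = [[99.2], [99.2], [98.7], [], [99.2]]
        hset = _call(bin_lists, identity_cutoff=99.0)
        got = [(b.start, b.end, b.median_identity, b.n_bins) for b in hset]
        assert got == [(0, 2 * BS, 99.2, 2), (4 * BS, 5 * BS, 99.2, 1)]

    def test_all_bins_empty_gives_no_blocks(self):
        assert len(_call([[], [], []])) == 0

    def test_empty_record_list_is_valid_empty_set(self):
        hset = call_haploblocks([], HaploblockParams(), {"chr1S": 20_000_000})
        assert isinstance(hset, HaploblockSet) and len(hset) == 0

    def test_unknown_merge_mode_rejected(self):
        with pytest.raises(ValueError, match="merge_mode"):
            HaploblockParams(merge_mode="fuzzy")

    def test_threshold_mode_bridges_distinct_medians(self):
        bin_lists = [[96.0], [97.5], [94.0], [96.2]]
        hset = _call(bin_lists, identity_cutoff=95.0, merge_mode="threshold")
        got = [(b.start, b.end, b.median_identity, b.n_bins) for b in hset]
        # bins 0-1 merge (median of 96.0, 97.5), bin 2 fails, bin 3 alone
        assert got == [(0, 2 * BS, 96.75, 2), (3 * BS, 4 * BS, 96.2, 1)]

    def test_short_alignments_are_discarded_first(self):
        records = [_rec(0, 30_000, 99.0), _rec(40_000, 55_000, 80.0)]  # 15 kb decoy
        hset = call_haploblocks(
            records, HaploblockParams(identity_cutoff=95.0), {"chr1S": BS}
        )
        assert [(b.median_identity, b.n_alignments) for b in hset] == [(99.0, 1)]

    def test_terminal_block_truncated_to_chromosome_length(self):
        hset = _call([[99.5], [99.5]], chrom_len=BS + 1_500_000)
        assert [(b.start, b.end) for b in hset] == [(0, BS + 1_500_000)]

    @pytest.mark.parametrize("mode", ["identical_median", "threshold"])
    def test_oracle_equivalence_on_random_instances(self, mode, rng):
        for trial in range(120):
            bin_lists = random_bin_instance(rng)
            cutoff = float(rng.choice([92.0, 95.0, 97.5]))
            min_bins = int(rng.integers(1, 3))
            chrom_len = len(bin_lists) * BS - (0 if rng.random() < 0.5 else 1_000_000)
            hset = _call(
                bin_lists,
                chrom_len=chrom_len,
                identity_cutoff=cutoff,
                merge_mode=mode,
                min_bins=min_bins,
            )
            expected = oracle_call(bin_lists, BS, chrom_len, cutoff, mode, 2, min_bins)
            got = [
                (b.start, b.end, b.median_identity, b.n_bins, b.n_alignments)
                for b in hset
            ]
            assert got == expected, f"trial {trial} mode {mode}"


class TestInvariants:
    @pytest.mark.parametrize("mode", ["identical_median", "threshold"])
    def test_blocks_disjoint_sorted_bin_aligned_in_bounds(self, mode, rng):
        for _ in range(30):
            bin_lists = random_bin_instance(rng)
            chrom_len = len(bin_lists) * BS - 700_000
            hset = _call(bin_lists, chrom_len=chrom_len, merge_mode=mode)
            prev_end = -1
            for b in hset:
                assert b.start % BS == 0
                assert b.end % BS == 0 or b.end == chrom_len
                # disjoint and sorted: abutting half-open blocks are fine
                assert b.start >= prev_end
                assert 0 <= b.start < b.end <= chrom_len
                prev_end = b.end

    def test_coverage_monotone_in_cutoff(self, rng):
        for _ in range(15):
            bin_lists = random_bin_instance(rng, p_empty=0.2)
            chrom_len = len(bin_lists) * BS
            lengths = {"chr1S": chrom_len}
            covs = [
                genome_coverage(
                    _call(bin_lists, identity_cutoff=c, merge_mode="threshold"), lengths
                )
                for c in (92.0, 95.0, 98.0)
            ]
            assert covs[0] >= covs[1] >= covs[2]

    def test_coverage_of_partition_is_total(self):
        lengths = {"chr1S": 40_000_000}
        blocks = [
            Haploblock("chr1S", 0, 15_000_000, 99.0, 3, 5),
            Haploblock("chr1S", 15_000_000, 40_000_000, 98.0, 5, 9),
        ]
        hset = HaploblockSet("r", "q", HaploblockParams(), blocks)
        assert genome_coverage(hset, lengths) == 100.0


class TestCoverageAndSummary:
    def _set(self, blocks):
        return HaploblockSet("r", "q", HaploblockParams(), blocks)

    def test_single_block_fraction(self):
        hset = self._set([Haploblock("chr1S", 0, 5_000_000, 99.0, 1, 1)])
        assert genome_coverage(hset, {"chr1S": 50_000_000}) == 10.0

    def test_empty_set_is_zero(self):
        assert genome_coverage(self._set([]), {"chr1S": 10}) == 0.0

    def test_block_beyond_chromosome_is_error(self):
        hset = self._set([Haploblock("chr1S", 0, 5_000_000, 99.0, 1, 1)])
        with pytest.raises(ValueError, match="beyond"):
            genome_coverage(hset, {"chr1S": 4_000_000})

    def test_matches_bitmap_oracle(self, rng):
        length = 1_000_000
        starts = np.sort(rng.choice(np.arange(0, length, 1000), size=20, replace=False))
        blocks = []
        for i, s in enumerate(starts):
            e = int(min(s + rng.integers(100, 900), length))
            blocks.append(Haploblock("chr1S", int(s), e, 99.0, 1, 1))
        hset = self._set(blocks)
        mask = bitmap_coverage([(b.start, b.end) for b in blocks], length)
        assert genome_coverage(hset, {"chr1S": length}) == pytest.approx(
            100.0 * mask.sum() / length
        )

    def test_summary_counts_and_mean(self):
        hset = self._set(
            [
                Haploblock("chr1S", 0, 5_000_000, 99.0, 1, 1),
                Haploblock("chr2S", 0, 15_000_000, 99.0, 3, 4),
            ]
        )
        s = block_summary(hset)
        assert s["count"] == 2
        assert s["mean_length"] == 10_000_000
        assert s["per_chrom"] == {"chr1S": 1, "chr2S": 1}

    def test_summary_of_empty_set(self):
        s = block_summary(self._set([]))
        assert s["count"] == 0 and s["mean_length"] is None

    def test_summary_matches_recomputation(self, rng):
        blocks = []
        pos = 0
        for i in range(100):
            pos += int(rng.integers(1, 50)) * 1000
            ln = int(rng.integers(1, 30)) * 1000
            blocks.append(Haploblock("chr1S", pos, pos + ln, 99.0, 1, 1))
            pos += ln
        s = block_summary(self._set(blocks))
        lengths = [b.end - b.start for b in blocks]
        assert s["count"] == 100
        assert s["mean_length"] == pytest.approx(sum(lengths) / 100)
        assert s["min_length"] == min(lengths) and s["max_length"] == max(lengths)


def _hset_from(intervals, ref="ref", qry="q"):
    blocks = [
        Haploblock("chr1S", s, e, 99.0, 1, 1, id=f"b{i}")
        for i, (s, e) in enumerate(intervals)
    ]
    return HaploblockSet(ref, qry, HaploblockParams(), blocks)


class TestIntersect:
    def test_pairwise_overlap(self):
        a = _hset_from([(0, 10_000_000)], qry="A")
        b = _hset_from([(5_000_000, 15_000_000)], qry="B")
        (iv,) = intersect_haploblock_sets([a, b])
        assert (iv.chrom, iv.start, iv.end) == ("chr1S", 5_000_000, 10_000_000)
        assert iv.attributes["median_0_A"] == "99.0"

    def test_any_empty_set_gives_empty_result(self):
        a = _hset_from([(0, 10_000_000)])
        b = _hset_from([])
        assert intersect_haploblock_sets([a, b]) == []

    def test_mismatched_reference_labels_rejected(self):
        a = _hset_from([(0, 1000)], ref="lon")
        b = _hset_from([(0, 1000)], ref="sha")
        with pytest.raises(ValueError, match="reference"):
            intersect_haploblock_sets([a, b])

    def test_three_sets_match_bitmap_and_oracle(self, rng):
        length = 500_000
        for _ in range(20):
            sets, masks = [], []
            for _ in range(3):
                pos, ivs = 0, []
                while pos < length - 2000:
                    pos += int(rng.integers(0, 5000))
                    end = min(pos + int(rng.integers(1, 8000)), length)
                    if end > pos:
                        ivs.append((pos, end))
                    pos = end + 1  # keep blocks disjoint, sometimes abutting
                sets.append(_hset_from(ivs))
                masks.append(bitmap_coverage(ivs, length))
            result = intersect_haploblock_sets(sets)
            got = bitmap_coverage([(iv.start, iv.end) for iv in result], length)
            expected = masks[0] & masks[1] & masks[2]
            assert np.array_equal(got, expected)
            # output disjoint and sorted
            for a, b in zip(result, result[1:]):
                assert a.end < b.start or a.chrom != b.chrom


class TestAssociate:
    def test_partial_overlap_associates(self):
        hset = _hset_from([(0, 5_000_000)])
        f = GenomeInterval("chr1S", 4_900_000, 5_100_000, id="g1")
        assoc = associate_intervals(hset, [f])
        assert assoc["g1"].start == 0

    def test_feature_outside_all_blocks_is_none(self):
        hset = _hset_from([(0, 5_000_000)])
        f = GenomeInterval("chr1S", 5_000_000, 5_000_100, id="g1")  # abutting
        assert associate_intervals(hset, [f])["g1"] is None

    def test_tie_resolved_to_larger_overlap_then_leftmost(self):
        hset = _hset_from([(0, 1000), (1000, 3000)])
        f = GenomeInterval("chr1S", 500, 2500, id="g1")  # 500 vs 1500 bp
        assert associate_intervals(hset, [f])["g1"].start == 1000
        g = GenomeInterval("chr1S", 500, 1500, id="g2")  # 500 vs 500 bp tie
        assert associate_intervals(hset, [g])["g2"].start == 0

    def test_matches_quadratic_oracle(self, rng):
        length = 2_000_000
        for _ in range(10):
            pos, ivs = 0, []
            while pos < length - 2000 and len(ivs) < 60:
                pos += int(rng.integers(1, 20000))
                end = min(pos + int(rng.integers(1, 30000)), length)
                ivs.append((pos, end))
                pos = end + int(rng.integers(1, 10000))
            hset = _hset_from(ivs)
            feats = []
            for i in range(200):
                s = int(rng.integers(0, length - 1))
                feats.append(
                    GenomeInterval("chr1S", s, s + int(rng.integers(1, 40000)), id=f"f{i}")
                )
            assoc = associate_intervals(hset, feats)
            expected = quadratic_overlaps(feats, hset.blocks)
            for f in feats:
                want = expected[f.id]
                got = assoc[f.id]
                if want is None:
                    assert got is None
                else:
                    assert got is hset.blocks[want]


class TestTsvRoundTrip:
    def test_block_table_round_trip(self, tmp_path):
        hset = _hset_from([(0, 5_000_000), (10_000_000, 20_000_000)], ref="lon", qry="sha")
        p = tmp_path / "blocks.tsv"
        write_haploblocks_tsv(hset, p, version="0.1.0")
        back = read_haploblocks_tsv(p)
        assert back.reference_genome == "lon" and back.query_genome == "sha"
        assert [(b.chrom, b.start, b.end, b.median_identity, b.n_bins, b.n_alignments)
                for b in back] == [
            (b.chrom, b.start, b.end, b.median_identity, b.n_bins, b.n_alignments)
            for b in hset
        ]
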