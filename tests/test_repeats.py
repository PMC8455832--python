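"""Depth-anomaly locus detection, segmentation, copy counting and ORFs."""

import numpy as np
import pytest

from sdrkit.io_formats import AlignmentRecord, DepthTrack, GenomicInterval, SequenceRecord
from sdrkit.repeats import (
    OrfRecord,
    RepeatLocus,
    RepeatScanParams,
    annotate_proximity,
    count_copies,
    detect_high_coverage_loci,
    find_orfs,
    segment_locus,
)
from sdrkit import synthetic as syn

STOP_SPACER = "TTAA" * 30  # stops in all six frames, no ATG


def subject_hit(subject, s_start, s_end, query="locus"):
    return AlignmentRecord(
        query_id=query, subject_id=subject, pident=95.0,
        aln_len=s_end - s_start + 1, mismatches=0, gap_opens=0,
        q_start=1, q_end=s_end - s_start + 1, s_start=s_start, s_end=s_end,
        evalue=0.0, bitscore=2.0 * (s_end - s_start + 1), gaps=0,
    )


class TestDetect:
    def test_constant_track_no_loci(self):
        track = DepthTrack("r", np.full(5000, 30.0))
        assert detect_high_coverage_loci(track) == []

    def test_short_spike_dropped_by_min_length(self):
        depths = np.full(5000, 30.0)
        depths[1000:1050] = 3000.0  # 50 bp only
        loci = detect_high_coverage_loci(DepthTrack("r", depths))
        assert loci == []

    def test_planted_locus_boundaries_within_one_window(self):
        for seed in range(5):
            track, truth = syn.gen_depth_track(
                50_000, 30.0, [(20_001, 29_300, 100.0)], noise_sd=3.0, seed=seed)
            (locus,) = detect_high_coverage_loci(track)
            start, end, _fold = truth.repeat_loci[0]
            assert abs(locus.interval.start - start) <= 100
            assert abs(locus.interval.end - end) <= 100
            assert locus.mean_fold == pytest.approx(100.0, rel=0.1)

    def test_merge_gap_bridges_dips(self):
        depths = np.full(10_000, 30.0)
        depths[2000:4000] = 900.0
        depths[4300:6000] = 900.0  # 300 bp dip < merge_gap
        (locus,) = detect_high_coverage_loci(DepthTrack("r", depths))
        assert locus.interval.start <= 2101 and locus.interval.end >= 5901

    def test_zero_background_rejected(self):
        with pytest.raises(ValueError, match="background"):
            detect_high_coverage_loci(DepthTrack("r", np.zeros(1000)))

    def test_matches_per_window_bruteforce(self, rng):
        # detect+segment agree with a direct window-threshold scan
        params = RepeatScanParams(window=50, merge_gap=0, min_locus_len=50)
        for _ in range(10):
            depths = np.full(3000, 20.0)
            for _ in range(int(rng.integers(0, 4))):
                s = int(rng.integers(0, 2500))
                e = s + int(rng.integers(100, 400))
                depths[s:e] = 20.0 * float(rng.integers(10, 50))
            track = DepthTrack("r", depths)
            bg = float(np.median(depths))
            means = depths[:3000 - 3000 % 50].reshape(-1, 50).mean(axis=1)
            flagged = means >= params.fold_threshold * bg
            covered = np.zeros(len(means), dtype=bool)
            for locus in detect_high_coverage_loci(track, params):
                w0 = (locus.interval.start - 1) // 50
                w1 = (locus.interval.end - 1) // 50
                covered[w0:w1 + 1] = True
            np.testing.assert_array_equal(covered, flagged)


class TestSegment:
    def test_uniform_locus_single_high_segment(self):
        depths = np.full(10_000, 30.0)
        depths[2000:5000] = 900.0
        track = DepthTrack("r", depths)
        (locus,) = detect_high_coverage_loci(track)
        segments = segment_locus(track, locus)
        assert len(segments) == 1
        assert segments[0][1] == "high"
        assert (segments[0][0].start, segments[0][0].end) == (
            locus.interval.start, locus.interval.end)

    def test_planted_dip_segmented_at_window_resolution(self):
        depths = np.full(20_000, 30.0)
        depths[2000:10_000] = 900.0
        depths[5000:5400] = 30.0  # internal low patch (mosaic half)
        track = DepthTrack("r", depths)
        (locus,) = detect_high_coverage_loci(track)
        segments = segment_locus(track, locus)
        labels = [lbl for _, lbl in segments]
        assert labels == ["high", "low", "high"]
        low = segments[1][0]
        assert abs(low.start - 5001) <= 100 and abs(low.end - 5400) <= 100
        # segments partition the locus
        assert segments[0][0].start == locus.interval.start
        assert segments[-1][0].end == locus.interval.end
        for (a, _), (b, _) in zip(segments, segments[1:]):
            assert b.start == a.end + 1

    def test_edge_dip_labelled_low(self):
        # a locus interval whose trailing edge is low coverage (as happens
        # when an externally supplied interval over-reaches the repeat)
        depths = np.full(10_000, 30.0)
        depths[2000:5600] = 900.0
        track = DepthTrack("r", depths)
        locus = RepeatLocus(
            interval=GenomicInterval("r", 2001, 6000), mean_fold=30.0)
        segments = segment_locus(track, locus)
        assert segments[-1][1] == "low"
        assert segments[0][1] == "high"
        assert segments[-1][0].end == 6000


class TestCountCopies:
    def test_no_hits(self):
        assert count_copies([]) == 0

    def test_merge_semantics(self):
        hits = [
            subject_hit("c1", 1000, 2000),
            subject_hit("c1", 5000, 6000),
            subject_hit("c1", 9000, 10_000),
        ]
        assert count_copies(hits) == 3
        overlapping = [subject_hit("c1", 1000, 2000), subject_hit("c1", 1500, 2500)]
        assert count_copies(overlapping) == 1

    def test_invariant_under_order_and_splitting(self, rng):
        hits = [subject_hit("c1", 1000 + 3000 * i, 2500 + 3000 * i) for i in range(5)]
        base = count_copies(hits)
        shuffled = list(hits)
        rng.shuffle(shuffled)
        assert count_copies(shuffled) == base
        split = []
        for h in hits:
            mid = (h.s_start + h.s_end) // 2
            split.append(subject_hit("c1", h.s_start, mid + 100))
            split.append(subject_hit("c1", mid - 100, h.s_end))
        assert count_copies(split) == base

    def test_planted_copies_counted(self, rng):
        starts = np.cumsum(rng.integers(2000, 5000, size=40)) + 10_000
        hits = [subject_hit("asm", int(s), int(s) + 1500) for s in starts]
        assert count_copies(hits) == 40


def orf_cassette(n_aa):
    """ATG + (n_aa - 1) sense codons + stop: an ORF of n_aa residues."""
    return "ATG" + "GCT" * (n_aa - 1) + "TAA"


def brute_force_orfs(seq, min_aa):
    """All-substring scan: most-upstream ATG per in-frame stop, both strands."""
    from Bio.Seq import Seq

    found = set()
    n = len(seq)
    for strand, s in (("+", seq), ("-", str(Seq(seq).reverse_complement()))):
        for frame in range(3):
            last_stop = frame - 3
            i = frame
            while i <= len(s) - 3:
                codon = s[i:i + 3]
                if "N" not in codon and codon in {"TAA", "TAG", "TGA"}:
                    # most-upstream ATG strictly after the previous stop
                    atg = None
                    for j in range(last_stop + 3, i, 3):
                        cj = s[j:j + 3]
                        if "N" not in cj and cj == "ATG":
                            atg = j
                            break
                    if atg is not None:
                        aa = (i + 2 - atg + 1) // 3 - 1
                        if aa >= min_aa:
                            if strand == "+":
                                found.add((strand, atg + 1, i + 3, aa))
                            else:
                                found.add((strand, n - (i + 2), n - atg, aa))
                    last_stop = i
                i += 3
    return found


class TestFindOrfs:
    def test_no_atg_no_orfs(self):
        rec = SequenceRecord(id="s", seq="GCTGCTGCTTAAGCT" * 30)
        assert find_orfs(rec, min_aa=1) == []

    def test_constructed_100aa_reported_99aa_not(self):
        seq100 = STOP_SPACER + orf_cassette(100) + STOP_SPACER
        seq99 = STOP_SPACER + orf_cassette(99) + STOP_SPACER
        assert len(find_orfs(SequenceRecord(id="a", seq=seq100))) == 1
        assert find_orfs(SequenceRecord(id="b", seq=seq99)) == []
        (orf,) = find_orfs(SequenceRecord(id="a", seq=seq100))
        assert orf.aa_length == 100
        assert orf.end - orf.start + 1 == 303

    def test_reverse_strand_symmetry(self):
        from Bio.Seq import Seq

        fwd = STOP_SPACER + orf_cassette(120) + STOP_SPACER
        rev = str(Seq(fwd).reverse_complement())
        (a,) = find_orfs(SequenceRecord(id="f", seq=fwd))
        (b,) = find_orfs(SequenceRecord(id="r", seq=rev))
        assert a.strand == "+" and b.strand == "-"
        assert a.aa_length == b.aa_length == 120
        assert (b.start, b.end) == (len(rev) - a.end + 1, len(rev) - a.start + 1)

    def test_n_codons_never_match(self):
        seq = STOP_SPACER + "ATN" + "GCT" * 120 + "TNA" + STOP_SPACER
        assert find_orfs(SequenceRecord(id="n", seq=seq), min_aa=50) == []

    def test_agrees_with_bruteforce_scan(self, rng):
        for _ in range(8):
            seq = "".join(rng.choice(list("ACGTN"), size=int(rng.integers(300, 3000)),
                                     p=[0.24, 0.24, 0.24, 0.24, 0.04]))
            got = {
                (o.strand, o.start, o.end, o.aa_length)
                for o in find_orfs(SequenceRecord(id="x", seq=seq), min_aa=10)
            }
            assert got == brute_force_orfs(seq, 10)


class TestProximity:
    def locus(self, start, end, seq="chr"):
        return RepeatLocus(interval=GenomicInterval(seq, start, end), mean_fold=50.0)

    def test_upstream_window_flagged(self):
        gene = GenomicInterval("chr", 100_000, 103_000, strand="+")
        (ann,) = annotate_proximity([self.locus(70_000, 80_000)], arr17_gene=gene)
        assert ann["upstream_of_ARR17"]
        assert 15_000 <= ann["gap_to_ARR17"] <= 40_000

    def test_far_locus_not_flagged(self):
        gene = GenomicInterval("chr", 200_000, 203_000, strand="+")
        (ann,) = annotate_proximity([self.locus(50_000, 60_000)], arr17_gene=gene)
        assert not ann["upstream_of_ARR17"]

    def test_overlapping_locus_not_upstream(self):
        gene = GenomicInterval("chr", 100_000, 103_000, strand="+")
        (ann,) = annotate_proximity([self.locus(99_000, 101_000)], arr17_gene=gene)
        assert ann["gap_to_ARR17"] == 0
        assert not ann["upstream_of_ARR17"]

    def test_strand_aware_upstream(self):
        gene = GenomicInterval("chr", 100_000, 103_000, strand="-")
        # 5' of a minus-strand gene lies to its right
        (ann,) = annotate_proximity([self.locus(120_000, 125_000)], arr17_gene=gene)
        assert ann["upstream_of_ARR17"]
        (ann2,) = annotate_proximity([self.locus(70_000, 80_000)], arr17_gene=gene)
        assert not ann2["upstream_of_ARR17"]

    def test_adjacent_to_repeats(self):
        feats = [GenomicInterval("chr", 30_000, 31_200)]
        (near,) = annotate_proximity([self.locus(33_000, 40_000)],
                                     repeat_clusters=feats)
        assert near["adjacent_to_repeats"]
        (far,) = annotate_proximity([self.locus(50_000, 60_000)],
                                    repeat_clusters=feats)
        assert not far["adjacent_to_repeats"]
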