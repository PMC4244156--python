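"""Evidence classification: library stats, windows, pair and spanning-read classes."""

import numpy as np
import pysam
import pytest

from indelgt import (
    EvidenceConfig,
    EvidenceCounts,
    IndelSite,
    LibraryStats,
    PairClass,
    SpanClass,
    classify_pair,
    classify_spanning_read,
    collect_evidence,
    insert_stats,
    estimate_library_stats,
    relevant_region,
)
from indelgt.evidence import (
    AlignedSegmentSummary,
    LibraryStatsUnavailable,
    PairSummary,
    SpanningRead,
)

from conftest import make_bam

LIB = LibraryStats(mu=500.0, sigma=50.0, read_len=100)
CFG = EvidenceConfig()
DEL_SITE = IndelSite.deletion("chr1", 10_000, 10_400)
INS_SITE = IndelSite.insertion("chr1", 10_000, 300)


class TestLibraryStats:
    def test_zero_variance(self):
        stats = insert_stats([500, 500, 500], read_lens=[100, 100])
        assert (stats.mu, stats.sigma, stats.read_len) == (500.0, 0.0, 100)

    def test_sample_sd_convention(self):
        stats = insert_stats([400, 500, 600])
        assert stats.mu == pytest.approx(500.0)
        assert stats.sigma == pytest.approx(100.0)  # ddof=1

    def test_outlier_trimming(self):
        inserts = [500] * 50 + [490, 510] * 25 + [100_000]
        stats = insert_stats(inserts)
        assert stats.mu == pytest.approx(500.0, abs=1.0)

    def test_no_proper_pairs_is_an_error(self):
        with pytest.raises(LibraryStatsUnavailable):
            insert_stats([])

    def test_bam_estimation_and_min_pairs(self, tmp_path):
        specs = []
        for i in range(120):
            specs.append({"qname": f"p{i}", "pos": 1000 + i, "cigar": "100M",
                          "mate_pos": 1000 + i + 400, "tlen": 500})
        path = make_bam(tmp_path / "lib.bam", specs)
        with pysam.AlignmentFile(path) as bam:
            for rec in bam:
                pass
        # records lack the proper-pair flag; set it through a rewritten stream
        with pysam.AlignmentFile(path) as bam:
            recs = []
            for rec in bam:
                rec.is_proper_pair = True
                recs.append(rec)
        stats = estimate_library_stats(iter(recs))
        assert stats.mu == pytest.approx(500.0)
        assert stats.read_len == 100
        with pytest.raises(LibraryStatsUnavailable):
            estimate_library_stats(iter(recs[:10]))


class TestRelevantRegion:
    def test_deletion_window(self):
        assert relevant_region(DEL_SITE, LIB, CFG) == (9350, 11050)

    def test_insertion_window(self):
        site = IndelSite.insertion("chr1", 10_000, 300)
        assert relevant_region(site, LIB, CFG) == (9350, 10650)

    def test_clipped_at_contig_start(self):
        site = IndelSite.deletion("chr1", 100, 200)
        start, _ = relevant_region(site, LIB, CFG)
        assert start == 0


def _pair(left_start, left_end, right_start, right_end, **kw):
    return PairSummary(
        both_mapped=True,
        left_start=left_start,
        left_end=left_end,
        right_start=right_start,
        right_end=right_end,
        insert=float(right_end - left_start),
        **kw,
    )


class TestClassifyPair:
    def test_deletion_discordant_support(self):
        # insert 905 vs expectation mu + L = 900, within 3 sigma
        pair = _pair(9600, 9700, 10405, 10505)
        assert classify_pair(pair, DEL_SITE, LIB, CFG) is PairClass.DISCORDANT_SUPPORT

    def test_deletion_concordant(self):
        pair = _pair(9800, 9900, 10210, 10310)  # insert 510 ~ mu
        assert classify_pair(pair, DEL_SITE, LIB, CFG) is PairClass.CONCORDANT

    def test_single_end_mapped_is_insertion_evidence_only(self):
        pair = PairSummary(both_mapped=False, left_start=9900, left_end=10000)
        assert classify_pair(pair, INS_SITE, LIB, CFG) is PairClass.SINGLE_END_MAPPED
        assert classify_pair(pair, DEL_SITE, LIB, CFG) is PairClass.UNINFORMATIVE

    def test_oversized_insert_is_invalid(self):
        pair = _pair(8000, 8100, 12900, 13000)  # insert 5000
        assert classify_pair(pair, DEL_SITE, LIB, CFG) is PairClass.INVALID

    def test_insertion_discordant_has_short_insert(self):
        site = IndelSite.insertion("chr1", 10_000, 300)
        # expectation mu - L = 200
        pair = _pair(9900, 9960, 10060, 10110)  # insert 210
        assert classify_pair(pair, site, LIB, CFG) is PairClass.DISCORDANT_SUPPORT

    def test_non_fr_orientation_uninformative(self):
        pair = _pair(9600, 9700, 10405, 10505, fr_orientation=False)
        assert classify_pair(pair, DEL_SITE, LIB, CFG) is PairClass.UNINFORMATIVE

    def test_non_encompassing_uninformative(self):
        pair = _pair(8000, 8100, 8410, 8510)  # far left of the site
        assert classify_pair(pair, DEL_SITE, LIB, CFG) is PairClass.UNINFORMATIVE

    def test_malformed_summary_rejected(self):
        with pytest.raises(ValueError, match="badpair"):
            PairSummary(both_mapped=True, left_start=100, left_end=50, name="badpair")

    def test_every_pair_gets_exactly_one_class(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            start = int(rng.integers(9000, 11000))
            insert = int(rng.integers(150, 6000))
            pair = PairSummary(
                both_mapped=bool(rng.random() < 0.9),
                left_start=start,
                left_end=start + 100,
                right_start=start + insert - 100,
                right_end=start + insert,
                insert=float(insert),
            )
            assert classify_pair(pair, DEL_SITE, LIB, CFG) in PairClass


class TestClassifySpanningRead:
    def test_split_read_at_both_breakpoints(self):
        read = SpanningRead((
            AlignedSegmentSummary(9953, 10003, left_clip=0, right_clip=50),
            AlignedSegmentSummary(10398, 10448, left_clip=50, right_clip=0),
        ))
        assert classify_spanning_read(read, DEL_SITE, CFG) is SpanClass.SPLIT

    def test_soft_clip_near_breakpoint_is_partial(self):
        read = SpanningRead((AlignedSegmentSummary(9930, 10012, right_clip=18),))
        assert classify_spanning_read(read, DEL_SITE, CFG) is SpanClass.PARTIAL

    def test_fully_mapped_over_breakpoint(self):
        read = SpanningRead((AlignedSegmentSummary(9950, 10050),))
        assert classify_spanning_read(read, DEL_SITE, CFG) is SpanClass.FULL

    def test_clip_beyond_slack_is_not_evidence(self):
        read = SpanningRead((AlignedSegmentSummary(9940, 10020, right_clip=20),))
        # clip boundary 20 bp past p1 (> slack 15) and not end-to-end: NONE
        assert classify_spanning_read(read, DEL_SITE, CFG) is SpanClass.NONE

    def test_tiny_clip_counts_as_end_to_end(self):
        read = SpanningRead((AlignedSegmentSummary(9950, 10047, right_clip=3),))
        assert classify_spanning_read(read, DEL_SITE, CFG) is SpanClass.FULL

    def test_split_not_used_for_insertions(self):
        read = SpanningRead((
            AlignedSegmentSummary(9953, 10003, right_clip=50),
            AlignedSegmentSummary(10398, 10448, left_clip=50),
        ))
        assert classify_spanning_read(read, INS_SITE, CFG) is not SpanClass.SPLIT


def _toy_site_specs():
    """Ten-template crafted fixture around DEL chr1:10000-10400.

    By hand: 2 discordant pairs, 3 concordant pairs, 1 split read, 2 fully
    mapped reads, 1 low-quality pair (excluded), 1 irrelevant pair.
    """
    specs = []
    # 2 discordant pairs (insert 905 ~ mu + L)
    for k in range(2):
        specs.append({"qname": f"disc{k}", "pos": 9600 + k, "cigar": "100M",
                      "mate_pos": 10405 + k, "tlen": 905})
        specs.append({"qname": f"disc{k}", "pos": 10405 + k, "cigar": "100M",
                      "mate_pos": 9600 + k, "tlen": -905, "read1": False,
                      "reverse": True})
    # 3 concordant pairs spanning p1 (insert 510)
    for k in range(3):
        specs.append({"qname": f"conc{k}", "pos": 9700 + k, "cigar": "100M",
                      "mate_pos": 10110 + k, "tlen": 510})
        specs.append({"qname": f"conc{k}", "pos": 10110 + k, "cigar": "100M",
                      "mate_pos": 9700 + k, "tlen": -510, "read1": False,
                      "reverse": True})
    # 1 split read (mate unmapped so the pair adds nothing)
    specs.append({"qname": "split0", "pos": 9953, "cigar": "50M50S",
                  "mate_unmapped": True})
    specs.append({"qname": "split0", "pos": 10398, "cigar": "50S50M",
                  "mate_unmapped": True, "supplementary": True})
    # 2 fully mapped spanning reads (mates unmapped)
    specs.append({"qname": "full0", "pos": 9950, "cigar": "100M", "mate_unmapped": True})
    specs.append({"qname": "full1", "pos": 10350, "cigar": "100M", "mate_unmapped": True})
    # both mates MAPQ 0: excluded from every count
    specs.append({"qname": "lowq", "pos": 9950, "cigar": "100M", "mapq": 0,
                  "mate_pos": 10360, "tlen": 510})
    specs.append({"qname": "lowq", "pos": 10360, "cigar": "100M", "mapq": 0,
                  "mate_pos": 9950, "tlen": -510, "read1": False, "reverse": True})
    # irrelevant distant pair inside the window but spanning nothing
    specs.append({"qname": "far0", "pos": 9360, "cigar": "100M",
                  "mate_pos": 9770, "tlen": 510})
    return specs


class TestCollectEvidence:
    def test_crafted_fixture_matches_hand_classification(self, tmp_path):
        path = make_bam(tmp_path / "toy.bam", _toy_site_specs())
        with pysam.AlignmentFile(path) as bam:
            counts = collect_evidence(bam, DEL_SITE, LIB, CFG)
        assert counts == EvidenceCounts(
            n_discordant=2, n_concordant=3, n_single_end_mapped=0,
            n_split=1, n_partial=0, n_full=2,
        )

    def test_empty_region_gives_zero_counts(self, tmp_path):
        path = make_bam(tmp_path / "empty.bam", [
            {"qname": "r0", "pos": 100, "cigar": "100M", "mate_pos": 510, "tlen": 510}
        ])
        site = IndelSite.deletion("chr1", 15_000, 15_400)
        with pysam.AlignmentFile(path) as bam:
            assert collect_evidence(bam, site, LIB, CFG) == EvidenceCounts()

    def test_unknown_contig_skipped_with_zero_counts(self, tmp_path):
        path = make_bam(tmp_path / "contig.bam", _toy_site_specs())
        site = IndelSite.deletion("chrX", 10_000, 10_400)
        with pysam.AlignmentFile(path) as bam:
            assert collect_evidence(bam, site, LIB, CFG) == EvidenceCounts()

    def test_determinism(self, tmp_path):
        path = make_bam(tmp_path / "det.bam", _toy_site_specs())
        with pysam.AlignmentFile(path) as bam:
            first = collect_evidence(bam, DEL_SITE, LIB, CFG)
            second = collect_evidence(bam, DEL_SITE, LIB, CFG)
        assert first == second

    def test_adding_a_read_is_monotone(self, tmp_path):
        base = _toy_site_specs()
        extra = base + [
            {"qname": "extra_full", "pos": 9955, "cigar": "100M", "mate_unmapped": True}
        ]
        p1 = make_bam(tmp_path / "a.bam", base)
        p2 = make_bam(tmp_path / "b.bam", extra)
        with pysam.AlignmentFile(p1) as bam:
            before = collect_evidence(bam, DEL_SITE, LIB, CFG)
        with pysam.AlignmentFile(p2) as bam:
            after = collect_evidence(bam, DEL_SITE, LIB, CFG)
        assert all(a >= b for a, b in zip(after.as_tuple(), before.as_tuple()))
        assert after.n_full == before.n_full + 1

    def test_multi_alignment_counted_once(self, tmp_path):
        # the same template duplicated as a supplementary alignment
        specs = [
            {"qname": "dup", "pos": 9950, "cigar": "100M", "mate_unmapped": True},
            {"qname": "dup", "pos": 9952, "cigar": "2S98M", "mate_unmapped": True,
             "supplementary": True},
        ]
        path = make_bam(tmp_path / "dup.bam", specs)
        with pysam.AlignmentFile(path) as bam:
            counts = collect_evidence(bam, DEL_SITE, LIB, CFG)
        assert counts.n_full == 1
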