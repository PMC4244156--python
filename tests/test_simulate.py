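"""Diploid simulator: truth genotypes, haplotype surgery, read sampling."""

import numpy as np
import pysam
import pytest

from indelgt import (
    EvidenceConfig,
    IndelSite,
    LibraryStats,
    SimConfig,
    assign_truth_genotypes,
    build_haplotypes,
    collect_evidence,
    random_deletion_sites,
    random_reference,
    simulate_individual_bam,
    simulate_paired_reads,
    simulate_trio_truth,
    write_fastq,
    write_truth_bam,
)
from indelgt.evaluate import trio_discordance
from indelgt.features import mean_region_depth, region_depth
from indelgt.simulate import Haplotype, _apply_events


class TestTruthGenotypes:
    def test_frequencies_match_within_sampling_error(self):
        rng = np.random.default_rng(1)
        sites = [IndelSite.deletion("ref", 1000 * i, 1000 * i + 100) for i in range(1, 101)]
        cfg = SimConfig(n_individuals=100, genotype_freqs=(0.7, 0.2, 0.1))
        truth = assign_truth_genotypes(sites, cfg, rng)
        n = truth.genotypes.size  # 10,000 draws
        for g, p in enumerate((0.7, 0.2, 0.1)):
            observed = int((truth.genotypes == g).sum())
            sd = np.sqrt(n * p * (1 - p))
            assert abs(observed - n * p) <= 3 * sd

    def test_degenerate_frequencies(self):
        rng = np.random.default_rng(0)
        sites = [IndelSite.deletion("ref", 100, 200)]
        cfg = SimConfig(n_individuals=50, genotype_freqs=(1.0, 0.0, 0.0))
        truth = assign_truth_genotypes(sites, cfg, rng)
        assert (truth.genotypes == 0).all()

    def test_seed_determinism(self):
        sites = [IndelSite.deletion("ref", 1000 * i, 1000 * i + 100) for i in range(1, 21)]
        cfg = SimConfig(n_individuals=10)
        a = assign_truth_genotypes(sites, cfg, np.random.default_rng(42))
        b = assign_truth_genotypes(sites, cfg, np.random.default_rng(42))
        assert (a.genotypes == b.genotypes).all()
        assert (a.hap_choice == b.hap_choice).all()

    def test_invalid_frequencies_rejected(self):
        with pytest.raises(ValueError):
            SimConfig(genotype_freqs=(0.5, 0.2, 0.2))


class TestHaplotypeSurgery:
    REF = "AAAACCCCGGGG"
    SITE = IndelSite.deletion("ref", 4, 8)

    def test_homozygous_deletion_removes_from_both(self):
        h0, h1 = build_haplotypes(self.REF, [self.SITE], [2], [0])
        assert h0.seq == h1.seq == "AAAAGGGG"

    def test_heterozygous_deletion_hits_one_copy(self):
        h0, h1 = build_haplotypes(self.REF, [self.SITE], [1], [1])
        assert h0.seq == "AAAACCCCGGGG"
        assert h1.seq == "AAAAGGGG"

    def test_insertion_applied_at_point(self):
        site = IndelSite.insertion("ref", 4, 3, id="ins")
        h0, h1 = build_haplotypes(self.REF, [site], [2], [0], ins_seqs={"ins": "TTT"})
        assert h0.seq == "AAAATTTCCCCGGGG"

    def test_overlapping_deletions_rejected(self):
        sites = [
            IndelSite.deletion("ref", 2, 6, id="a"),
            IndelSite.deletion("ref", 4, 8, id="b"),
        ]
        with pytest.raises(ValueError, match="overlap"):
            build_haplotypes(self.REF, sites, [2, 2], [0, 0])

    def test_liftover_maps_across_a_deletion(self):
        hap = _apply_events(self.REF, [(self.SITE, None)])
        # haplotype positions 0..7 = AAAAGGGG; bases 4..8 come from ref 8..12
        segs = hap.ref_segments(2, 6)
        assert segs == [(0, 2, 2), (2, 4, 8)]


class TestReadSimulation:
    def _hap(self, n=100_000, seed=0):
        ref = random_reference(n, np.random.default_rng(seed))
        hap = _apply_events(ref, [])
        return ref, hap

    def test_pair_count_formula(self):
        ref, hap = self._hap()
        cfg = SimConfig(coverage=10.0, read_len=100)
        reads = simulate_paired_reads((hap, hap), cfg, np.random.default_rng(0), ref_len=len(ref))
        assert len(reads.hap) == 5000  # c*G / 2l

    def test_error_free_reads_are_exact_substrings(self, tmp_path):
        ref, hap = self._hap(20_000)
        cfg = SimConfig(coverage=1.0, error_rate=0.0, n_individuals=1)
        reads = simulate_paired_reads((hap, hap), cfg, np.random.default_rng(1), ref_len=len(ref))
        f1, f2 = tmp_path / "r1.fq", tmp_path / "r2.fq"
        write_fastq(reads, str(f1), str(f2), np.random.default_rng(2))
        comp = str.maketrans("ACGT", "TGCA")
        for path in (f1, f2):
            lines = path.read_text().splitlines()
            for i in range(1, len(lines), 4):
                seq = lines[i]
                assert seq in ref or seq.translate(comp)[::-1] in ref

    def test_fastq_seed_determinism(self, tmp_path):
        ref, hap = self._hap(20_000)
        cfg = SimConfig(coverage=1.0, n_individuals=1)
        outs = []
        for run in ("a", "b"):
            reads = simulate_paired_reads((hap, hap), cfg, np.random.default_rng(5), ref_len=len(ref))
            f1 = tmp_path / f"{run}1.fq"
            f2 = tmp_path / f"{run}2.fq"
            write_fastq(reads, str(f1), str(f2), np.random.default_rng(6))
            outs.append(f1.read_bytes() + f2.read_bytes())
        assert outs[0] == outs[1]

    def test_short_haplotype_rejected(self):
        ref = random_reference(500, np.random.default_rng(0))
        hap = _apply_events(ref, [])
        with pytest.raises(ValueError, match="too short"):
            simulate_paired_reads((hap, hap), SimConfig(), np.random.default_rng(0), ref_len=500)


class TestTruthAlignments:
    def test_realized_depth_matches_target_coverage(self, tmp_path):
        rng = np.random.default_rng(3)
        ref = random_reference(60_000, rng)
        path = str(tmp_path / "flat.bam")
        cfg = SimConfig(coverage=6.0)
        simulate_individual_bam(path, ref, [], [], [], cfg, rng)
        with pysam.AlignmentFile(path) as bam:
            depth = mean_region_depth(region_depth(bam, "ref", 25_000, 35_000))
        assert depth == pytest.approx(6.0, rel=0.1)

    def test_deletion_footprint_in_alignments(self, tmp_path):
        """A homozygous deletion leaves ~0 depth inside and split/discordant reads."""
        rng = np.random.default_rng(4)
        ref = random_reference(60_000, rng)
        site = IndelSite.deletion("ref", 30_000, 30_800)
        cfg = SimConfig(coverage=12.0)
        path = str(tmp_path / "del.bam")
        simulate_individual_bam(path, ref, [site], [2], [0], cfg, rng)
        lib = LibraryStats(500, 50, 100)
        with pysam.AlignmentFile(path) as bam:
            inside = mean_region_depth(region_depth(bam, "ref", 30_100, 30_700))
            flank = mean_region_depth(region_depth(bam, "ref", 28_000, 29_000))
            counts = collect_evidence(bam, site, lib, EvidenceConfig())
        assert inside < 0.1 * flank
        assert counts.n_discordant >= 3
        assert counts.n_split + counts.n_partial >= 1
        assert counts.n_concordant == 0 and counts.n_full == 0

    def test_heterozygous_deletion_halves_interval_depth(self, tmp_path):
        rng = np.random.default_rng(5)
        ref = random_reference(60_000, rng)
        site = IndelSite.deletion("ref", 30_000, 31_000)
        cfg = SimConfig(coverage=20.0)
        path = str(tmp_path / "het.bam")
        simulate_individual_bam(path, ref, [site], [1], [0], cfg, rng)
        with pysam.AlignmentFile(path) as bam:
            inside = mean_region_depth(region_depth(bam, "ref", 30_200, 30_800))
            flank = mean_region_depth(region_depth(bam, "ref", 28_000, 29_500))
        assert inside == pytest.approx(0.5 * flank, rel=0.25)

    def test_insertion_produces_clips_and_short_inserts(self, tmp_path):
        rng = np.random.default_rng(6)
        ref = random_reference(60_000, rng)
        site = IndelSite.insertion("ref", 30_000, 400, id="ins0")
        cfg = SimConfig(coverage=12.0)
        path = str(tmp_path / "ins.bam")
        simulate_individual_bam(
            path, ref, [site], [2], [0], cfg, rng,
            ins_seqs={"ins0": random_reference(400, rng)},
        )
        lib = LibraryStats(500, 50, 100)
        with pysam.AlignmentFile(path) as bam:
            counts = collect_evidence(bam, site, lib, EvidenceConfig())
        assert counts.n_partial >= 1
        assert counts.n_discordant >= 1
        assert counts.n_full == 0

    def test_bam_is_sorted_and_indexed(self, tmp_path):
        rng = np.random.default_rng(7)
        ref = random_reference(40_000, rng)
        path = str(tmp_path / "sorted.bam")
        simulate_individual_bam(path, ref, [], [], [], SimConfig(coverage=2.0), rng)
        with pysam.AlignmentFile(path) as bam:
            positions = [r.reference_start for r in bam.fetch("ref", 0, 40_000)]
        assert positions == sorted(positions)


class TestTrioSimulation:
    def test_child_inherits_one_allele_per_parent(self):
        rng = np.random.default_rng(8)
        sites = [IndelSite.deletion("ref", 1000 * i, 1000 * i + 200) for i in range(1, 201)]
        cfg = SimConfig(genotype_freqs=(0.4, 0.4, 0.2))
        trio = simulate_trio_truth(sites, cfg, rng)
        metrics = trio_discordance(zip(*trio.genotypes))
        assert metrics.n_discordant == 0
        # child dosage bounded by parental dosage
        gf, gm, gc = trio.genotypes
        assert (gc <= np.ceil(gf / 2) + np.ceil(gm / 2)).all()
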