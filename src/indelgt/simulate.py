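"""Diploid paired-end read simulator with planted indels of known genotype.

The simulator is the training-data source for the genotyper: diploid
individuals receive deletions/insertions at given sites (genotype 0/1/2,
heterozygous carriers get the event on one arbitrary haplotype), paired-end
fragments are sampled from both haplotypes with Normal(insert_mean,
insert_sd) lengths and a uniform per-base substitution error, and the truth
genotypes are kept.  Defaults follow the study conditions: read length 100,
mean insert 500 (sd 50), 2% base error, genotype frequencies 70/20/10
(wild-type / het / hom).

Two outputs are supported: paired FASTQ (for an external aligner) and
"truth placement" alignments — a coordinate-sorted BAM built directly from
the known fragment origins, lifted from haplotype to reference coordinates,
with split/soft-clipped records at indel junctions and unmapped mates
inside long insertions, i.e. what an ideal soft-clipping aligner would
produce.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pysam

from .evidence import IndelKind, IndelSite

logger = logging.getLogger("indelgt")

__all__ = [
    "SimConfig",
    "TruthMatrix",
    "Haplotype",
    "ReadSet",
    "random_reference",
    "random_deletion_sites",
    "random_insertion_sites",
    "hwe_genotype_probs",
    "assign_truth_genotypes",
    "simulate_trio_truth",
    "random_insertion_seqs",
    "build_haplotypes",
    "simulate_paired_reads",
    "write_fastq",
    "write_truth_bam",
    "simulate_individual_bam",
]

_BASES = np.frombuffer(b"ACGT", dtype="S1")
_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Minimum mapped length for a supplementary (split) alignment record.
MIN_SPLIT_SEGMENT = 20


@dataclass(frozen=True)
class SimConfig:
    """Simulation conditions for one cohort."""

    coverage: float = 6.0
    read_len: int = 100
    insert_mean: float = 500.0
    insert_sd: float = 50.0
    error_rate: float = 0.02
    genotype_freqs: tuple[float, float, float] = (0.7, 0.2, 0.1)
    n_individuals: int = 10
    seed: int = 0

    def __post_init__(self) -> None:
        if abs(sum(self.genotype_freqs) - 1.0) > 1e-9:
            raise ValueError("genotype_freqs must sum to 1")
        if not (0 <= self.error_rate < 1):
            raise ValueError("error_rate must be in [0, 1)")
        if self.coverage <= 0 or self.read_len <= 0:
            raise ValueError("coverage and read_len must be positive")
        if self.insert_mean <= 2 * self.read_len:
            raise ValueError("insert_mean must exceed twice the read length")


@dataclass
class TruthMatrix:
    """Simulated genotypes (N individuals x M sites) plus het haplotype choice."""

    genotypes: np.ndarray
    hap_choice: np.ndarray
    individuals: list[str]
    site_ids: list[str]

    def __post_init__(self) -> None:
        self.genotypes = np.asarray(self.genotypes, dtype=int)
        self.hap_choice = np.asarray(self.hap_choice, dtype=int)
        if self.genotypes.shape != (len(self.individuals), len(self.site_ids)):
            raise ValueError("genotype matrix shape mismatch")
        if not np.isin(self.genotypes, (0, 1, 2)).all():
            raise ValueError("genotypes must be 0/1/2")

    def row(self, individual: str) -> np.ndarray:
        return self.genotypes[self.individuals.index(individual)]


# ---------------------------------------------------------------------------
# References and sites
# ---------------------------------------------------------------------------

def random_reference(length: int, rng: np.random.Generator) -> str:
    """I.i.d. uniform A/C/G/T reference of the given length."""
    return rng.choice(_BASES, size=length).tobytes().decode()


def _place_sites(
    n: int,
    ref_len: int,
    lengths: np.ndarray,
    rng: np.random.Generator,
    min_gap: int,
    kind: IndelKind,
) -> list[IndelSite]:
    """Place non-overlapping sites left to right with at least min_gap spacing."""
    occupied = lengths if kind is IndelKind.DEL else np.zeros_like(lengths)
    needed = occupied.sum() + (n + 1) * min_gap
    if needed > ref_len:
        raise ValueError(f"reference of {ref_len} bp too short for {n} sites")
    slack = ref_len - occupied.sum() - (n + 1) * min_gap
    cuts = np.sort(rng.integers(0, slack + 1, size=n))
    sites = []
    cursor = 0
    for i in range(n):
        p1 = int(cuts[i] + cursor + (i + 1) * min_gap)
        if kind is IndelKind.DEL:
            sites.append(IndelSite.deletion("ref", p1, p1 + int(lengths[i]), id=f"del{i:03d}"))
            cursor += int(lengths[i])
        else:
            sites.append(IndelSite.insertion("ref", p1, int(lengths[i]), id=f"ins{i:03d}"))
    return sites


def _log_uniform_lengths(
    n: int, low: int, high: int, rng: np.random.Generator
) -> np.ndarray:
    return np.exp(rng.uniform(np.log(low), np.log(high), size=n)).round().astype(int)


def random_deletion_sites(
    n: int,
    ref_len: int,
    rng: np.random.Generator,
    min_len: int = 50,
    max_len: int = 5000,
    min_gap: int = 2000,
) -> list[IndelSite]:
    """Non-overlapping deletions with log-uniform lengths in [min_len, max_len]."""
    return _place_sites(n, ref_len, _log_uniform_lengths(n, min_len, max_len, rng), rng, min_gap, IndelKind.DEL)


def random_insertion_sites(
    n: int,
    ref_len: int,
    rng: np.random.Generator,
    min_len: int = 50,
    max_len: int = 5000,
    min_gap: int = 2000,
) -> list[IndelSite]:
    return _place_sites(n, ref_len, _log_uniform_lengths(n, min_len, max_len, rng), rng, min_gap, IndelKind.INS)


def random_insertion_seqs(
    sites: Sequence[IndelSite], rng: np.random.Generator
) -> dict[str, str]:
    """One random inserted sequence per insertion site (shared by all carriers)."""
    return {
        s.label: random_reference(s.length, rng)
        for s in sites
        if s.kind is IndelKind.INS
    }


# ---------------------------------------------------------------------------
# Truth genotypes
# ---------------------------------------------------------------------------

def hwe_genotype_probs(allele_freqs: np.ndarray) -> np.ndarray:
    """Hardy-Weinberg genotype probabilities per site, columns (g0, g1, g2)."""
    q = np.asarray(allele_freqs, float)
    return np.stack([(1 - q) ** 2, 2 * q * (1 - q), q ** 2], axis=1)


def assign_truth_genotypes(
    sites: Sequence[IndelSite],
    cfg: SimConfig,
    rng: np.random.Generator,
    allele_freqs: np.ndarray | None = None,
    individuals: Sequence[str] | None = None,
) -> TruthMatrix:
    """I.i.d. genotype draws per (individual, site).

    By default every site uses cfg.genotype_freqs; with per-site allele
    frequencies the draws are Hardy-Weinberg.  Heterozygotes get a random
    haplotype assignment (the event goes on one arbitrary copy).
    """
    m = len(sites)
    n = cfg.n_individuals if individuals is None else len(individuals)
    if allele_freqs is None:
        probs = np.tile(np.asarray(cfg.genotype_freqs, float), (m, 1))
    else:
        if len(allele_freqs) != m:
            raise ValueError("one allele frequency per site required")
        probs = hwe_genotype_probs(allele_freqs)
    if np.any(np.abs(probs.sum(axis=1) - 1.0) > 1e-9):
        raise ValueError("genotype probabilities must sum to 1")
    u = rng.random((n, m))
    cum = np.cumsum(probs, axis=1)
    genotypes = (u[:, :, None] > cum[None, :, :-1]).sum(axis=2)
    hap_choice = rng.integers(0, 2, size=(n, m))
    names = list(individuals) if individuals else [f"ind{i:02d}" for i in range(n)]
    return TruthMatrix(genotypes, hap_choice, names, [s.label for s in sites])


def simulate_trio_truth(
    sites: Sequence[IndelSite],
    cfg: SimConfig,
    rng: np.random.Generator,
    allele_freqs: np.ndarray | None = None,
) -> TruthMatrix:
    """Father and mother drawn i.i.d.; the child inherits one allele from each.

    The resulting trio is Mendelian-consistent by construction, which is the
    baseline for trio-discordance evaluation.
    """
    parents = assign_truth_genotypes(
        sites, cfg, rng, allele_freqs=allele_freqs, individuals=["father", "mother"]
    )
    gf, gm = parents.genotypes
    a_f = (rng.random(len(sites)) < gf / 2).astype(int)
    a_m = (rng.random(len(sites)) < gm / 2).astype(int)
    gc = a_f + a_m
    genotypes = np.vstack([gf, gm, gc])
    hap_choice = np.vstack([parents.hap_choice, np.where(a_f == 1, 0, 1)])
    return TruthMatrix(genotypes, hap_choice, ["father", "mother", "child"], [s.label for s in sites])


# ---------------------------------------------------------------------------
# Haplotype construction with liftover
# ---------------------------------------------------------------------------

@dataclass
class Haplotype:
    """One chromosome copy plus the block map back to reference coordinates.

    Blocks partition the haplotype; each either mirrors a reference interval
    or is inserted sequence anchored at a reference position.
    """

    seq: str
    block_starts: np.ndarray  # haplotype start of each block, plus total length
    block_ref: np.ndarray     # reference coordinate of block start (or insertion anchor)
    block_is_ref: np.ndarray

    def __len__(self) -> int:
        return int(self.block_starts[-1])

    def ref_segments(
        self, start: int, end: int
    ) -> list[tuple[int, int, int | None]]:
        """Pieces of the haplotype interval [start, end) in read coordinates.

        Returns (q0, q1, ref_start) per piece; ref_start is None for pieces
        that fall in inserted sequence (unmappable on the reference).
        """
        out = []
        i = int(np.searchsorted(self.block_starts, start, side="right")) - 1
        while i < len(self.block_is_ref) and self.block_starts[i] < end:
            h0 = max(start, int(self.block_starts[i]))
            h1 = min(end, int(self.block_starts[i + 1]))
            if h1 > h0:
                if self.block_is_ref[i]:
                    out.append((h0 - start, h1 - start, int(self.block_ref[i]) + h0 - int(self.block_starts[i])))
                else:
                    out.append((h0 - start, h1 - start, None))
            i += 1
        return out


def _apply_events(
    ref: str, events: Sequence[tuple[IndelSite, str | None]]
) -> Haplotype:
    parts: list[str] = []
    starts: list[int] = []
    refs: list[int] = []
    is_ref: list[bool] = []
    cursor = 0
    hpos = 0

    def push(seq: str, ref_start: int, mapped: bool) -> None:
        nonlocal hpos
        if not seq:
            return
        parts.append(seq)
        starts.append(hpos)
        refs.append(ref_start)
        is_ref.append(mapped)
        hpos += len(seq)

    for site, ins_seq in events:
        if site.p1 < cursor:
            raise ValueError(f"overlapping indel sites at {site.label}")
        if site.p2 > len(ref):
            raise ValueError(f"site {site.label} outside the reference")
        push(ref[cursor:site.p1], cursor, True)
        if site.kind is IndelKind.DEL:
            cursor = site.p2
        else:
            if not ins_seq:
                raise ValueError(f"no inserted sequence for {site.label}")
            push(ins_seq, site.p1, False)
            cursor = site.p1
    push(ref[cursor:], cursor, True)
    starts.append(hpos)
    return Haplotype(
        seq="".join(parts),
        block_starts=np.asarray(starts, dtype=np.int64),
        block_ref=np.asarray(refs, dtype=np.int64),
        block_is_ref=np.asarray(is_ref, dtype=bool),
    )


def build_haplotypes(
    ref: str,
    sites: Sequence[IndelSite],
    genotypes: Sequence[int],
    hap_choice: Sequence[int],
    ins_seqs: Mapping[str, str] | None = None,
) -> tuple[Haplotype, Haplotype]:
    """Apply one individual's genotypes to the reference.

    Genotype 2 puts the event on both haplotypes, 1 on the chosen one, 0 on
    neither.  Sites must be non-overlapping and sorted by position;
    insertion sequences come from ``ins_seqs`` keyed by site label.
    """
    order = sorted(range(len(sites)), key=lambda i: (sites[i].p1, sites[i].p2))
    haps = []
    for h in (0, 1):
        events = []
        for i in order:
            g = int(genotypes[i])
            if g == 2 or (g == 1 and int(hap_choice[i]) == h):
                seq = (ins_seqs or {}).get(sites[i].label)
                events.append((sites[i], seq))
        haps.append(_apply_events(ref, events))
    return haps[0], haps[1]


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

@dataclass
class ReadSet:
    """Sampled fragments of one individual, before error injection.

    Each pair is the first/last read_len bases of a fragment on one
    haplotype; ``r1_is_left`` records which sequenced mate is the
    left/forward one (FR orientation).
    """

    haplotypes: tuple[Haplotype, Haplotype]
    hap: np.ndarray       # 0/1 per pair
    start: np.ndarray     # fragment start on its haplotype
    frag: np.ndarray      # fragment length
    r1_is_left: np.ndarray
    cfg: SimConfig
    sample: str = "sample"


def simulate_paired_reads(
    haplotypes: tuple[Haplotype, Haplotype],
    cfg: SimConfig,
    rng: np.random.Generator,
    ref_len: int,
    sample: str = "sample",
) -> ReadSet:
    """Sample round(c*G / 2l) fragment pairs across the two haplotypes.

    Fragment lengths are Normal(insert_mean, insert_sd) truncated below at
    2*read_len; starts are uniform wherever the fragment fits.
    """
    l = cfg.read_len
    n_pairs = int(round(cfg.coverage * ref_len / (2 * l)))
    min_len = min(len(h) for h in haplotypes)
    if min_len <= cfg.insert_mean + 6 * cfg.insert_sd:
        raise ValueError("haplotype too short for the insert-size distribution")
    hap = rng.binomial(1, 0.5, size=n_pairs)
    frag = np.maximum(
        2 * l, np.rint(rng.normal(cfg.insert_mean, cfg.insert_sd, size=n_pairs)).astype(int)
    )
    limits = np.array([len(haplotypes[0]), len(haplotypes[1])])[hap] - frag
    frag = np.where(limits < 0, 2 * l, frag)  # clamp rare oversized fragments
    limits = np.maximum(limits, 0)
    start = (rng.random(n_pairs) * (limits + 1)).astype(np.int64)
    r1_is_left = rng.random(n_pairs) < 0.5
    return ReadSet(tuple(haplotypes), hap, start, frag, r1_is_left, cfg, sample)


def _revcomp(seq: str) -> str:
    return "".join(_COMPLEMENT[b] for b in reversed(seq))


def _mutate(seq: str, rng: np.random.Generator, e: float) -> str:
    if e <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype="S1").copy()
    hits = np.nonzero(rng.random(len(arr)) < e)[0]
    if len(hits):
        # substitute with one of the three other bases
        originals = arr[hits]
        subs = _BASES[rng.integers(0, 4, size=len(hits))]
        clash = subs == originals
        while clash.any():
            subs[clash] = _BASES[rng.integers(0, 4, size=int(clash.sum()))]
            clash = subs == originals
        arr[hits] = subs
    return arr.tobytes().decode()


def write_fastq(reads: ReadSet, path1: str, path2: str, rng: np.random.Generator) -> None:
    """Paired FASTQ with substitution errors; mate 2 is reverse-complemented."""
    l = reads.cfg.read_len
    e = reads.cfg.error_rate
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i in range(len(reads.hap)):
            hap = reads.haplotypes[reads.hap[i]]
            s, f = int(reads.start[i]), int(reads.frag[i])
            left = _mutate(hap.seq[s:s + l], rng, e)
            right = _mutate(hap.seq[s + f - l:s + f], rng, e)
            if reads.r1_is_left[i]:
                r1, r2 = left, _revcomp(right)
            else:
                r1, r2 = _revcomp(right), left
            name = f"{reads.sample}_p{i}"
            q = "I" * l
            f1.write(f"@{name}/1\n{r1}\n+\n{q}\n")
            f2.write(f"@{name}/2\n{r2}\n+\n{q}\n")


# ---------------------------------------------------------------------------
# Truth-placement alignments
# ---------------------------------------------------------------------------

def _records_for_read(
    hap: Haplotype, s: int, e: int
) -> list[tuple[int, int, int, int, int]]:
    """Mapped segments (q0, q1, ref_start, left_clip, right_clip) of read [s, e)."""
    l = e - s
    segs = []
    for q0, q1, ref_start in hap.ref_segments(s, e):
        if ref_start is not None:
            segs.append((q0, q1, ref_start, q0, l - q1))
    return segs


def write_truth_bam(
    path: str,
    reads: ReadSet,
    ref_name: str = "ref",
    ref_len: int | None = None,
) -> str:
    """Coordinate-sorted, indexed BAM of ideal alignments for one individual.

    Reads crossing a deletion junction become a primary alignment with the
    longer side matched plus a supplementary record for the other side
    (when it is at least 20 bp); portions inside inserted sequence are
    soft-clipped, and reads entirely inside an insertion are unmapped (or
    dropped when the whole pair is).  SEQ is omitted ('*'): genotype
    evidence never reads base content.
    """
    cfg = reads.cfg
    l = cfg.read_len
    if ref_len is None:
        h0 = reads.haplotypes[0]
        lens = np.diff(h0.block_starts)
        ref_len = int((h0.block_ref + lens * h0.block_is_ref).max())
    header = pysam.AlignmentHeader.from_dict(
        {
            "HD": {"VN": "1.6", "SO": "coordinate"},
            "SQ": [{"SN": ref_name, "LN": int(ref_len)}],
            "RG": [{"ID": reads.sample, "SM": reads.sample}],
        }
    )
    records: list[pysam.AlignedSegment] = []
    for i in range(len(reads.hap)):
        hap = reads.haplotypes[reads.hap[i]]
        s, f = int(reads.start[i]), int(reads.frag[i])
        left_segs = _records_for_read(hap, s, s + l)
        right_segs = _records_for_read(hap, s + f - l, s + f)
        if not left_segs and not right_segs:
            continue  # whole pair inside inserted sequence

        name = f"{reads.sample}_p{i}"
        left_first = bool(reads.r1_is_left[i])

        def primary_of(segs):
            return max(segs, key=lambda t: t[1] - t[0]) if segs else None

        pl, pr = primary_of(left_segs), primary_of(right_segs)
        left_pos = pl[2] if pl else pr[2]
        right_pos = pr[2] if pr else pl[2]
        outer_start = min(left_pos, right_pos)
        outer_end = max(
            (pl[2] + pl[1] - pl[0]) if pl else 0,
            (pr[2] + pr[1] - pr[0]) if pr else 0,
        )
        tlen = outer_end - outer_start if pl and pr else 0

        for side, segs, primary in (("L", left_segs, pl), ("R", right_segs, pr)):
            is_left = side == "L"
            is_read1 = left_first == is_left
            mate_primary = pr if is_left else pl
            for seg in segs:
                if seg is not primary and (seg[1] - seg[0]) < MIN_SPLIT_SEGMENT:
                    continue
                rec = pysam.AlignedSegment(header)
                rec.query_name = name
                rec.reference_id = 0
                rec.reference_start = seg[2]
                rec.mapping_quality = 60
                cig = []
                if seg[3]:
                    cig.append((4, seg[3]))
                cig.append((0, seg[1] - seg[0]))
                if seg[4]:
                    cig.append((4, seg[4]))
                rec.cigartuples = cig
                rec.is_paired = True
                rec.is_read1 = is_read1
                rec.is_read2 = not is_read1
                rec.is_reverse = not is_left
                rec.mate_is_reverse = is_left
                rec.is_supplementary = seg is not primary
                if mate_primary is not None:
                    rec.next_reference_id = 0
                    rec.next_reference_start = mate_primary[2]
                    rec.mate_is_unmapped = False
                    if seg is primary and tlen:
                        rec.template_length = tlen if seg[2] == outer_start else -tlen
                    rec.is_proper_pair = seg is primary
                else:
                    rec.next_reference_id = 0
                    rec.next_reference_start = seg[2]
                    rec.mate_is_unmapped = True
                rec.set_tag("RG", reads.sample)
                records.append(rec)
            if not segs and mate_primary is not None:
                # this mate is entirely inside inserted sequence: unmapped record
                rec = pysam.AlignedSegment(header)
                rec.query_name = name
                rec.is_paired = True
                rec.is_read1 = left_first == is_left
                rec.is_read2 = not rec.is_read1
                rec.is_unmapped = True
                rec.reference_id = 0
                rec.reference_start = mate_primary[2]
                rec.next_reference_id = 0
                rec.next_reference_start = mate_primary[2]
                rec.mapping_quality = 0
                rec.set_tag("RG", reads.sample)
                records.append(rec)

    records.sort(key=lambda r: r.reference_start)
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(path)
    return path


def simulate_individual_bam(
    path: str,
    ref: str,
    sites: Sequence[IndelSite],
    genotypes: Sequence[int],
    hap_choice: Sequence[int],
    cfg: SimConfig,
    rng: np.random.Generator,
    ins_seqs: Mapping[str, str] | None = None,
    sample: str = "sample",
    ref_name: str = "ref",
) -> ReadSet:
    """Haplotypes -> fragments -> truth-placement BAM for one individual."""
    h0, h1 = build_haplotypes(ref, sites, genotypes, hap_choice, ins_seqs)
    reads = simulate_paired_reads((h0, h1), cfg, rng, ref_len=len(ref), sample=sample)
    write_truth_bam(path, reads, ref_name=ref_name, ref_len=len(ref))
    return reads
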