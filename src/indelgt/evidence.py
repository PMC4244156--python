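"""Read-evidence collection at known indel breakpoints.

A large deletion or insertion leaves several distinct footprints in
paired-end alignments: encompassing pairs whose insert size shifts by the
event length, reads split or soft-clipped at the breakpoints, pairs with one
unmapped mate (long insertions), and depressed read depth inside a deleted
interval.  This module fetches the reads near a site and tallies each of
those evidence categories per (individual, site).

Coordinates are 0-based half-open throughout: for a deletion ``p1`` is the
first deleted base and ``p2`` one past the last; for an insertion
``p1 == p2`` is the insertion point.
"""

from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pysam

logger = logging.getLogger("indelgt")

__all__ = [
    "IndelKind",
    "IndelSite",
    "LibraryStats",
    "EvidenceConfig",
    "PairClass",
    "SpanClass",
    "EvidenceCounts",
    "PairSummary",
    "AlignedSegmentSummary",
    "SpanningRead",
    "insert_stats",
    "estimate_library_stats",
    "relevant_region",
    "classify_pair",
    "classify_spanning_read",
    "collect_evidence",
    "LibraryStatsUnavailable",
]


class LibraryStatsUnavailable(RuntimeError):
    """Raised when insert-size statistics cannot be estimated from a BAM.

    Supply ``mu`` and ``sigma`` explicitly when the input has too few proper
    pairs (e.g. single-end data or a tiny region).
    """


class IndelKind(str, enum.Enum):
    DEL = "DEL"
    INS = "INS"


@dataclass(frozen=True)
class IndelSite:
    """One known indel: the unit of genotyping.

    ``length`` is ``p2 - p1`` for deletions and the inserted length for
    insertions (where ``p1 == p2``).
    """

    chrom: str
    p1: int
    p2: int
    kind: IndelKind
    length: int | None = None
    id: str | None = None

    def __post_init__(self) -> None:
        kind = IndelKind(self.kind)
        object.__setattr__(self, "kind", kind)
        if self.p1 < 0 or self.p2 < self.p1:
            raise ValueError(f"invalid breakpoints p1={self.p1}, p2={self.p2}")
        if kind is IndelKind.DEL:
            if self.p2 <= self.p1:
                raise ValueError("deletion requires p2 > p1")
            if self.length is None:
                object.__setattr__(self, "length", self.p2 - self.p1)
            elif self.length != self.p2 - self.p1:
                raise ValueError("deletion length must equal p2 - p1")
        else:
            if self.p1 != self.p2:
                raise ValueError("insertion requires p1 == p2")
            if self.length is None or self.length <= 0:
                raise ValueError("insertion requires a positive length")

    @classmethod
    def deletion(cls, chrom: str, p1: int, p2: int, id: str | None = None) -> "IndelSite":
        return cls(chrom, p1, p2, IndelKind.DEL, id=id)

    @classmethod
    def insertion(cls, chrom: str, pos: int, length: int, id: str | None = None) -> "IndelSite":
        return cls(chrom, pos, pos, IndelKind.INS, length=length, id=id)

    @property
    def label(self) -> str:
        return self.id or f"{self.chrom}:{self.p1}-{self.p2}:{self.kind.value}"


@dataclass(frozen=True)
class LibraryStats:
    """Insert-size distribution (mu, sigma) and read length of a library."""

    mu: float
    sigma: float
    read_len: int

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.sigma < 0 or self.read_len <= 0:
            raise ValueError("invalid library stats")


@dataclass(frozen=True)
class EvidenceConfig:
    """Tunables for evidence classification.

    n_sigma
        Half-width, in insert-size standard deviations, of the concordance /
        discordance windows (mu ± n_sigma*sigma).
    clip_slack
        Tolerance in bp when matching clip or split boundaries to
        breakpoints (``-c`` on the CLI, default 15).
    mapq_min
        Minimum mapping quality for a well-mapped read; a pair with both
        mates below this (or unmapped) is discarded.
    min_clip
        Soft clips shorter than this are treated as alignment noise rather
        than breakpoint evidence.
    window_pad
        Relevant-read window extension D; ``None`` means mu + n_sigma*sigma.
    """

    n_sigma: float = 3.0
    clip_slack: int = 15
    mapq_min: int = 20
    min_clip: int = 5
    window_pad: int | None = None

    def __post_init__(self) -> None:
        if self.n_sigma < 0 or self.clip_slack < 0 or self.mapq_min < 0 or self.min_clip < 0:
            raise ValueError("config values must be non-negative")
        if self.window_pad is not None and self.window_pad < 0:
            raise ValueError("window_pad must be non-negative")

    def pad(self, lib: LibraryStats) -> int:
        if self.window_pad is not None:
            return int(self.window_pad)
        return int(round(lib.mu + self.n_sigma * lib.sigma))


class PairClass(enum.Enum):
    DISCORDANT_SUPPORT = "discordant_support"
    CONCORDANT = "concordant"
    SINGLE_END_MAPPED = "single_end_mapped"
    INVALID = "invalid"
    UNINFORMATIVE = "uninformative"


class SpanClass(enum.Enum):
    SPLIT = "split"
    PARTIAL = "partial"
    FULL = "full"
    NONE = "none"


@dataclass
class EvidenceCounts:
    """Per (individual, site) tallies of the read-evidence categories."""

    n_discordant: int = 0
    n_concordant: int = 0
    n_single_end_mapped: int = 0
    n_split: int = 0
    n_partial: int = 0
    n_full: int = 0

    def __post_init__(self) -> None:
        for name, v in self.as_dict().items():
            if v < 0 or int(v) != v:
                raise ValueError(f"{name} must be a non-negative integer")

    def as_dict(self) -> dict[str, int]:
        return {
            "n_discordant": self.n_discordant,
            "n_concordant": self.n_concordant,
            "n_single_end_mapped": self.n_single_end_mapped,
            "n_split": self.n_split,
            "n_partial": self.n_partial,
            "n_full": self.n_full,
        }

    def __add__(self, other: "EvidenceCounts") -> "EvidenceCounts":
        return EvidenceCounts(
            *(a + b for a, b in zip(self.as_tuple(), other.as_tuple()))
        )

    def as_tuple(self) -> tuple[int, ...]:
        return (
            self.n_discordant,
            self.n_concordant,
            self.n_single_end_mapped,
            self.n_split,
            self.n_partial,
            self.n_full,
        )


# ---------------------------------------------------------------------------
# Library statistics
# ---------------------------------------------------------------------------

def insert_stats(
    inserts: Sequence[float], read_lens: Sequence[int] | None = None
) -> LibraryStats:
    """Insert-size mean/sd (sample sd, ddof=1) after Tukey outlier trimming.

    Values outside [Q1 - 3*IQR, Q3 + 3*IQR] are dropped before computing the
    moments; on tiny inputs the fences keep everything.  ``read_len`` is the
    modal read length, defaulting to 100 when not supplied.
    """
    arr = np.asarray(inserts, dtype=float)
    if arr.size == 0:
        raise LibraryStatsUnavailable(
            "no proper pairs found; specify --mu/--sigma explicitly"
        )
    q1, q3 = np.percentile(arr, [25, 75])
    iqr = q3 - q1
    kept = arr[(arr >= q1 - 3 * iqr) & (arr <= q3 + 3 * iqr)]
    if kept.size == 0:  # pragma: no cover - fences always keep the quartiles
        kept = arr
    mu = float(kept.mean())
    sigma = float(kept.std(ddof=1)) if kept.size > 1 else 0.0
    if read_lens is not None and len(read_lens) > 0:
        vals, counts = np.unique(np.asarray(read_lens, dtype=int), return_counts=True)
        read_len = int(vals[np.argmax(counts)])
    else:
        read_len = 100
    return LibraryStats(mu=mu, sigma=sigma, read_len=read_len)


def estimate_library_stats(
    alignments: "pysam.AlignmentFile | Iterable[pysam.AlignedSegment]",
    max_pairs: int = 10_000,
    min_pairs: int = 100,
) -> LibraryStats:
    """Estimate mu/sigma/read length from the first proper pairs in a BAM.

    Raises :class:`LibraryStatsUnavailable` when fewer than ``min_pairs``
    proper pairs are seen; in that case the user should supply mu and sigma
    explicitly.
    """
    records = alignments.fetch() if isinstance(alignments, pysam.AlignmentFile) else alignments
    inserts: list[float] = []
    read_lens: list[int] = []
    for rec in records:
        if rec.is_unmapped or rec.is_secondary or rec.is_supplementary:
            continue
        if rec.query_length:
            read_lens.append(rec.query_length)
        elif rec.infer_query_length():
            read_lens.append(rec.infer_query_length())
        if rec.is_proper_pair and rec.template_length > 0:
            inserts.append(float(rec.template_length))
            if len(inserts) >= max_pairs:
                break
    if len(inserts) < min_pairs:
        raise LibraryStatsUnavailable(
            f"only {len(inserts)} proper pairs found (< {min_pairs}); "
            "specify --mu/--sigma explicitly"
        )
    return insert_stats(inserts, read_lens)


# ---------------------------------------------------------------------------
# Relevant-read window
# ---------------------------------------------------------------------------

def relevant_region(
    site: IndelSite, lib: LibraryStats, cfg: EvidenceConfig
) -> tuple[int, int]:
    """[p1 - D, p2 + D] with D = window_pad, clipped at position 0.

    A read can belong to an indel-overlapping pair only if it starts within
    one maximal insert of a breakpoint, hence D defaults to mu + 3*sigma.
    """
    d = cfg.pad(lib)
    return max(0, site.p1 - d), site.p2 + d


# ---------------------------------------------------------------------------
# Pair classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PairSummary:
    """Geometry of one read pair, in reference coordinates.

    ``left_*`` refer to the leftmost-mapped mate; ``insert`` is the outer
    template span (|TLEN|).  For a single-end-mapped pair only the mapped
    mate's coordinates are meaningful.
    """

    both_mapped: bool
    left_start: int
    left_end: int
    right_start: int = 0
    right_end: int = 0
    insert: float = 0.0
    fr_orientation: bool = True
    name: str | None = None

    def __post_init__(self) -> None:
        if self.left_end < self.left_start or (
            self.both_mapped and self.right_end < self.right_start
        ):
            raise ValueError(f"malformed pair summary for record {self.name!r}")


def classify_pair(
    pair: PairSummary, site: IndelSite, lib: LibraryStats, cfg: EvidenceConfig
) -> PairClass:
    """Assign a pair to exactly one evidence category for ``site``.

    A both-mapped innie pair whose outer span covers a breakpoint is
    DISCORDANT_SUPPORT when its insert matches the indel-adjusted expectation
    mu + L (deletion) or mu - L (insertion) within n_sigma*sigma, and
    CONCORDANT when the insert matches plain mu; inserts beyond both windows
    are INVALID (likely mismapped) and one-mapped-mate pairs are evidence
    only at insertion sites.  When the two windows overlap (short events) the
    nearer centre wins, ties conservatively to CONCORDANT.
    """
    if not pair.both_mapped:
        if site.kind is IndelKind.INS:
            return PairClass.SINGLE_END_MAPPED
        return PairClass.UNINFORMATIVE
    if not pair.fr_orientation:
        return PairClass.UNINFORMATIVE

    l_adj = site.length if site.kind is IndelKind.DEL else -site.length
    halfwidth = cfg.n_sigma * lib.sigma
    if pair.insert > max(lib.mu, lib.mu + l_adj) + halfwidth:
        return PairClass.INVALID

    outer_start, outer_end = pair.left_start, max(pair.right_end, pair.left_start + pair.insert)
    spans_a_breakpoint = any(
        outer_start < b < outer_end for b in {site.p1, site.p2}
    )
    if not spans_a_breakpoint:
        return PairClass.UNINFORMATIVE

    # Discordant support additionally needs the mates on opposite sides of
    # the event (geometrically forced for a true indel-spanning fragment).
    c = cfg.clip_slack
    if site.kind is IndelKind.DEL:
        opposite = pair.left_end <= site.p1 + c and pair.right_start >= site.p2 - c
    else:
        opposite = pair.left_end <= site.p1 + c and pair.right_start >= site.p1 - c
    dev_disc = abs(pair.insert - lib.mu - l_adj)
    dev_conc = abs(pair.insert - lib.mu)
    disc_ok = opposite and dev_disc <= halfwidth
    conc_ok = dev_conc <= halfwidth
    if disc_ok and conc_ok:
        return PairClass.DISCORDANT_SUPPORT if dev_disc < dev_conc else PairClass.CONCORDANT
    if disc_ok:
        return PairClass.DISCORDANT_SUPPORT
    if conc_ok:
        return PairClass.CONCORDANT
    return PairClass.UNINFORMATIVE


# ---------------------------------------------------------------------------
# Spanning-read classification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class AlignedSegmentSummary:
    """One mapped segment of a read: reference span plus its soft clips."""

    ref_start: int
    ref_end: int
    left_clip: int = 0
    right_clip: int = 0


@dataclass(frozen=True)
class SpanningRead:
    """All mapped segments (primary + supplementary) of one physical read."""

    segments: tuple[AlignedSegmentSummary, ...]
    name: str | None = None


def classify_spanning_read(
    read: SpanningRead, site: IndelSite, cfg: EvidenceConfig
) -> SpanClass:
    """SPLIT / PARTIAL / FULL / NONE for one read at one site.

    SPLIT (deletions only): two mapped segments with inner edges within
    clip_slack of p1 and p2.  PARTIAL: a soft clip (>= min_clip bp) whose
    boundary lies within clip_slack of a breakpoint.  FULL: a single
    end-to-end segment (clips below min_clip) strictly covering a
    breakpoint.  Precedence SPLIT > PARTIAL > FULL keeps classes disjoint.
    """
    segs = sorted(read.segments, key=lambda s: s.ref_start)
    if not segs:
        return SpanClass.NONE
    c = cfg.clip_slack

    if site.kind is IndelKind.DEL and len(segs) >= 2:
        for i, a in enumerate(segs):
            for b in segs[i + 1:]:
                if abs(a.ref_end - site.p1) <= c and abs(b.ref_start - site.p2) <= c:
                    return SpanClass.SPLIT

    breakpoints = {site.p1, site.p2}
    for seg in segs:
        if seg.left_clip >= cfg.min_clip and any(
            abs(seg.ref_start - b) <= c for b in breakpoints
        ):
            return SpanClass.PARTIAL
        if seg.right_clip >= cfg.min_clip and any(
            abs(seg.ref_end - b) <= c for b in breakpoints
        ):
            return SpanClass.PARTIAL

    for seg in segs:
        end_to_end = seg.left_clip <= c and seg.right_clip <= c
        if end_to_end and any(seg.ref_start < b < seg.ref_end for b in breakpoints):
            return SpanClass.FULL
    return SpanClass.NONE


# ---------------------------------------------------------------------------
# BAM-level collection
# ---------------------------------------------------------------------------

def _segment_summary(rec: pysam.AlignedSegment) -> AlignedSegmentSummary:
    cig = rec.cigartuples or []
    left = cig[0][1] if cig and cig[0][0] in (4, 5) else 0
    right = cig[-1][1] if cig and cig[-1][0] in (4, 5) else 0
    return AlignedSegmentSummary(
        ref_start=rec.reference_start,
        ref_end=rec.reference_end,
        left_clip=left,
        right_clip=right,
    )


def _pair_summary(rec: pysam.AlignedSegment, read_len: int) -> PairSummary:
    """Pair geometry from a single primary record (mate may be off-region)."""
    if rec.mate_is_unmapped:
        return PairSummary(
            both_mapped=False,
            left_start=rec.reference_start,
            left_end=rec.reference_end,
            name=rec.query_name,
        )
    insert = abs(rec.template_length)
    if rec.reference_start <= rec.next_reference_start:
        left_start, left_end = rec.reference_start, rec.reference_end
        right_start = rec.next_reference_start
        right_end = max(right_start, left_start + insert)
        fr = (not rec.is_reverse) and rec.mate_is_reverse
    else:
        right_start, right_end = rec.reference_start, rec.reference_end
        left_start = rec.next_reference_start
        left_end = min(right_end, left_start + read_len)
        fr = rec.is_reverse and (not rec.mate_is_reverse)
    return PairSummary(
        both_mapped=True,
        left_start=left_start,
        left_end=left_end,
        right_start=right_start,
        right_end=right_end,
        insert=float(insert),
        fr_orientation=fr,
        name=rec.query_name,
    )


def collect_evidence(
    bam: pysam.AlignmentFile,
    site: IndelSite,
    lib: LibraryStats,
    cfg: EvidenceConfig | None = None,
) -> EvidenceCounts:
    """Fetch reads around ``site`` and tally the evidence categories.

    Pairs with both mates unmapped or both below ``mapq_min`` are discarded;
    each physical template contributes at most one pair class and each
    physical read one span class, regardless of multi-alignment.  A site on
    a contig absent from the header yields all-zero counts with a warning.
    """
    cfg = cfg or EvidenceConfig()
    if site.chrom not in bam.references:
        logger.warning("contig %s absent from BAM header; site %s skipped", site.chrom, site.label)
        return EvidenceCounts()
    start, end = relevant_region(site, lib, cfg)
    end = min(end, bam.get_reference_length(site.chrom))

    # (qname, mate-ordinal) -> segments; qname -> representative primary record
    segments: dict[tuple[str, int], list[AlignedSegmentSummary]] = {}
    seg_mapq: dict[tuple[str, int], int] = {}
    primaries: dict[str, dict[int, pysam.AlignedSegment]] = {}
    for rec in bam.fetch(site.chrom, start, end):
        if rec.is_secondary or rec.is_duplicate or rec.is_unmapped:
            continue
        mate = 2 if rec.is_read2 else 1
        key = (rec.query_name, mate)
        segments.setdefault(key, []).append(_segment_summary(rec))
        seg_mapq[key] = max(seg_mapq.get(key, 0), rec.mapping_quality)
        if not rec.is_supplementary:
            primaries.setdefault(rec.query_name, {})[mate] = rec

    counts = EvidenceCounts()

    for qname, mates in primaries.items():
        recs = list(mates.values())
        if all(r.mapping_quality < cfg.mapq_min for r in recs):
            continue  # pair quality filter: no well-mapped mate in hand
        # Representative: the leftmost mapped primary we have.
        rep = min(recs, key=lambda r: r.reference_start)
        pc = classify_pair(_pair_summary(rep, lib.read_len), site, lib, cfg)
        if pc is PairClass.DISCORDANT_SUPPORT:
            counts.n_discordant += 1
        elif pc is PairClass.CONCORDANT:
            counts.n_concordant += 1
        elif pc is PairClass.SINGLE_END_MAPPED:
            counts.n_single_end_mapped += 1

    for key, segs in segments.items():
        if seg_mapq.get(key, 0) < cfg.mapq_min:
            continue
        sc = classify_spanning_read(SpanningRead(tuple(segs), name=key[0]), site, cfg)
        if sc is SpanClass.SPLIT:
            counts.n_split += 1
        elif sc is SpanClass.PARTIAL:
            counts.n_partial += 1
        elif sc is SpanClass.FULL:
            counts.n_full += 1

    return counts
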