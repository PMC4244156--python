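"""Feature vectors for indel genotype classification.

Raw evidence counts depend on sequencing depth, so every site's counts are
normalized by the local coverage of its flanking regions before
classification.  Deletion vectors are ordered (discordant, concordant,
split, full, depth); insertion vectors (discordant, concordant,
single-end-mapped, partial, full).  Depth is informative only for deletions
(reads cannot map inside an insertion, so the reference interval is empty).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .evidence import (
    EvidenceConfig,
    EvidenceCounts,
    IndelKind,
    IndelSite,
    LibraryStats,
    collect_evidence,
    estimate_library_stats,
)

logger = logging.getLogger("indelgt")

__all__ = [
    "DepthProfile",
    "FeatureVector",
    "FEATURE_NAMES",
    "FEATURE_COLUMNS",
    "CoverageUnavailable",
    "mean_region_depth",
    "region_depth",
    "local_coverage",
    "global_mean_coverage",
    "build_feature_vector",
    "normalize_vector",
    "extract_feature_table",
    "write_feature_tsv",
    "read_feature_tsv",
]

#: Component order of the classifier input, per indel kind.
FEATURE_NAMES: dict[IndelKind, tuple[str, ...]] = {
    IndelKind.DEL: ("discordant", "concordant", "split", "full", "depth"),
    IndelKind.INS: ("discordant", "concordant", "single_end_mapped", "partial", "full"),
}

#: Generic column names used in the feature TSV (semantics depend on `kind`).
FEATURE_COLUMNS = ("f1", "f2", "f3", "f4", "f5")

#: Local coverage below eps (in x) triggers the sample-wide fallback.
COVERAGE_EPS = 0.5


class CoverageUnavailable(RuntimeError):
    pass


@dataclass(frozen=True)
class DepthProfile:
    """Per-base mapped-read coverage over one genomic interval."""

    chrom: str
    start: int
    end: int
    depth: np.ndarray

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValueError("empty region")
        if len(self.depth) != self.end - self.start:
            raise ValueError("depth array does not match region length")


@dataclass
class FeatureVector:
    """One normalized f=5 point in classifier space."""

    values: np.ndarray
    kind: IndelKind
    local_cov: float | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (5,):
            raise ValueError("feature vectors have exactly 5 components")
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("feature values must be finite and non-negative")


def mean_region_depth(profile: DepthProfile | Sequence[float]) -> float:
    """Average depth: sum of per-base coverage divided by region length."""
    depth = profile.depth if isinstance(profile, DepthProfile) else np.asarray(profile, float)
    if len(depth) == 0:
        raise ValueError("empty region has no mean depth")
    return float(np.sum(depth)) / len(depth)


def region_depth(bam: pysam.AlignmentFile, chrom: str, start: int, end: int) -> DepthProfile:
    """Aligned-base (CIGAR M/=/X) coverage over [start, end).

    Soft-clipped and deleted read bases do not contribute; secondary and
    duplicate records are skipped.
    """
    start = max(0, start)
    end = min(end, bam.get_reference_length(chrom))
    if end <= start:
        raise ValueError("empty region")
    diff = np.zeros(end - start + 1, dtype=np.int64)
    for rec in bam.fetch(chrom, start, end):
        if rec.is_unmapped or rec.is_secondary or rec.is_duplicate:
            continue
        for bs, be in rec.get_blocks():
            s, e = max(bs, start), min(be, end)
            if e > s:
                diff[s - start] += 1
                diff[e - start] -= 1
    return DepthProfile(chrom, start, end, np.cumsum(diff[:-1]))


def local_coverage(
    bam: pysam.AlignmentFile,
    site: IndelSite,
    lib: LibraryStats,
    cfg: EvidenceConfig | None = None,
) -> float:
    """Mean of the mean depths of the two breakpoint-flanking windows.

    Flanks are [p1-w, p1) and [p2, p2+w) with w = mu + n_sigma*sigma; for an
    insertion both abut the single breakpoint.  At a contig edge the
    surviving flank alone is used; two empty flanks raise
    :class:`CoverageUnavailable` (the caller falls back to the sample-wide
    mean).
    """
    cfg = cfg or EvidenceConfig()
    w = cfg.pad(lib)
    ref_len = bam.get_reference_length(site.chrom)
    flank_means = []
    for s, e in ((site.p1 - w, site.p1), (site.p2, site.p2 + w)):
        s, e = max(0, s), min(e, ref_len)
        if e > s:
            flank_means.append(mean_region_depth(region_depth(bam, site.chrom, s, e)))
    if not flank_means:
        raise CoverageUnavailable(f"no flanking sequence at site {site.label}")
    return float(np.mean(flank_means))


def global_mean_coverage(bam: pysam.AlignmentFile, read_len: int) -> float:
    """Sample-wide mean coverage estimate (mapped reads x read length / genome)."""
    stats = bam.get_index_statistics()
    mapped = sum(s.mapped for s in stats)
    total = sum(bam.get_reference_length(r) for r in bam.references)
    if total == 0:
        raise CoverageUnavailable("empty reference")
    return mapped * read_len / total


def build_feature_vector(
    counts: EvidenceCounts, depth: float, kind: IndelKind | str
) -> FeatureVector:
    """Assemble the raw (unnormalized) vector in canonical component order.

    ``depth`` is the mean depth over the deleted interval; it is ignored for
    insertions.
    """
    kind = IndelKind(kind)
    if kind is IndelKind.DEL:
        values = (counts.n_discordant, counts.n_concordant, counts.n_split, counts.n_full, depth)
    else:
        values = (
            counts.n_discordant,
            counts.n_concordant,
            counts.n_single_end_mapped,
            counts.n_partial,
            counts.n_full,
        )
    return FeatureVector(np.asarray(values, dtype=float), kind)


def normalize_vector(
    vector: FeatureVector,
    local_cov: float,
    fallback_cov: float | None = None,
    eps: float = COVERAGE_EPS,
) -> FeatureVector:
    """Divide every component by the local coverage.

    When the local coverage is below ``eps`` (a near-empty region) the
    sample-wide mean ``fallback_cov`` is used instead so the vector stays
    finite; with no fallback available this is an error naming the site.
    """
    if local_cov < 0:
        raise ValueError("negative coverage")
    lam = local_cov
    if lam < eps:
        if fallback_cov is None or fallback_cov <= 0:
            raise CoverageUnavailable(
                f"local coverage {local_cov:.3g} below {eps} and no fallback coverage"
            )
        lam = fallback_cov
    return FeatureVector(vector.values / lam, vector.kind, local_cov=lam)


# ---------------------------------------------------------------------------
# Pipeline: BAM + sites -> feature table
# ---------------------------------------------------------------------------

def extract_feature_table(
    bam: "pysam.AlignmentFile | str",
    sites: Sequence[IndelSite],
    lib: LibraryStats | None = None,
    cfg: EvidenceConfig | None = None,
    sample: str = "sample",
    labels: Sequence[int] | None = None,
) -> pd.DataFrame:
    """Normalized feature rows for every site of one individual.

    Columns: sample, site_id, kind, [label,] f1..f5, local_cov.  The deletion
    depth feature is the mean depth over [p1, p2) so homozygous-reference
    sites sit near 1.0 after normalization regardless of sequencing depth.
    """
    own = isinstance(bam, str)
    af = pysam.AlignmentFile(bam) if own else bam
    try:
        if lib is None:
            lib = estimate_library_stats(af)
        cfg = cfg or EvidenceConfig()
        fallback = global_mean_coverage(af, lib.read_len)
        rows = []
        for i, site in enumerate(sites):
            counts = collect_evidence(af, site, lib, cfg)
            if site.kind is IndelKind.DEL:
                depth = mean_region_depth(region_depth(af, site.chrom, site.p1, site.p2))
            else:
                depth = 0.0
            raw = build_feature_vector(counts, depth, site.kind)
            try:
                lam = local_coverage(af, site, lib, cfg)
            except CoverageUnavailable:
                lam = 0.0
            vec = normalize_vector(raw, lam, fallback_cov=fallback)
            row = {"sample": sample, "site_id": site.label, "kind": site.kind.value}
            if labels is not None:
                row["label"] = int(labels[i])
            row.update(dict(zip(FEATURE_COLUMNS, vec.values)))
            row["local_cov"] = vec.local_cov
            rows.append(row)
        return pd.DataFrame(rows)
    finally:
        if own:
            af.close()


def write_feature_tsv(table: pd.DataFrame, path: str) -> None:
    table.to_csv(path, sep="\t", index=False)


def read_feature_tsv(path: str) -> pd.DataFrame:
    table = pd.read_csv(path, sep="\t")
    required = {"sample", "site_id", "kind", *FEATURE_COLUMNS, "local_cov"}
    missing = required - set(table.columns)
    if missing:
        raise ValueError(f"feature TSV missing columns: {sorted(missing)}")
    return table
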