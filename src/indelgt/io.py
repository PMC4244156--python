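"""Site lists, genotype VCF output and run configuration plumbing.

Site input conventions: in VCF, POS is taken as the first deleted base and
END as the last (both 1-based), so a deletion maps to internal 0-based
half-open [POS-1, END); an insertion at POS with SVLEN maps to the point
p1 = p2 = POS-1.  The 4-column TSV (chrom, start, end, kind[, id, length])
uses the same 1-based inclusive convention.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import pandas as pd
import pysam

from . import __version__
from .evidence import EvidenceConfig, IndelKind, IndelSite
from .genotyper import GenotypeCall
from .simulate import SimConfig

logger = logging.getLogger("indelgt")

__all__ = [
    "SiteTable",
    "RunConfig",
    "read_sites",
    "write_sites_tsv",
    "write_genotype_vcf",
]


@dataclass
class SiteTable:
    """Ordered, uniquely-labelled indel sites in internal coordinates."""

    sites: list[IndelSite]
    source: str = "<memory>"
    n_skipped: int = 0

    def __post_init__(self) -> None:
        labels = [s.label for s in self.sites]
        if len(set(labels)) != len(labels):
            raise ValueError("site ids must be unique")
        self.sites = sorted(self.sites, key=lambda s: (s.chrom, s.p1, s.p2))

    def __iter__(self):
        return iter(self.sites)

    def __len__(self) -> int:
        return len(self.sites)


def _sites_from_vcf(path: str) -> tuple[list[IndelSite], int]:
    sites: list[IndelSite] = []
    skipped = 0
    with pysam.VariantFile(path) as vcf:
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                ref, alts = rec.ref or "", rec.alts or ()
                if alts and len(ref) > len(alts[0]):
                    svtype = "DEL"
                elif alts and len(ref) < len(alts[0]):
                    svtype = "INS"
            try:
                rid = rec.id or f"{rec.chrom}_{rec.pos}"
                if svtype == "DEL":
                    # pysam: rec.start = POS-1; rec.stop carries END when the
                    # record had one, else it is fabricated from the REF allele.
                    if rec.stop > rec.start + 1:
                        p2 = rec.stop
                    elif "SVLEN" in rec.info:
                        svlen = rec.info["SVLEN"]
                        if isinstance(svlen, tuple):
                            svlen = svlen[0]
                        p2 = rec.start + abs(int(svlen))
                    else:
                        raise ValueError("deletion without END or SVLEN")
                    sites.append(IndelSite.deletion(rec.chrom, rec.start, p2, id=rid))
                elif svtype == "INS":
                    svlen = rec.info.get("SVLEN")
                    if isinstance(svlen, tuple):
                        svlen = svlen[0]
                    if svlen is None and rec.alts and rec.alts[0][0] != "<":
                        svlen = len(rec.alts[0]) - len(rec.ref or "")
                    if not svlen:
                        raise ValueError("insertion without SVLEN")
                    sites.append(IndelSite.insertion(rec.chrom, rec.start, abs(int(svlen)), id=rid))
                else:
                    raise ValueError(f"unsupported SVTYPE {svtype!r}")
            except ValueError as exc:
                skipped += 1
                logger.info("skipping record %s:%d (%s)", rec.chrom, rec.pos, exc)
    return sites, skipped


def _sites_from_tsv(path: str) -> tuple[list[IndelSite], int]:
    table = pd.read_csv(path, sep="\t", comment="#")
    cols = {c.lower(): c for c in table.columns}
    needed = ("chrom", "start", "end", "kind")
    if not all(k in cols for k in needed):
        raise ValueError(f"site TSV needs columns {needed}, found {list(table.columns)}")
    sites: list[IndelSite] = []
    skipped = 0
    for i, row in table.iterrows():
        try:
            kind = IndelKind(str(row[cols["kind"]]).upper())
            rid = str(row[cols["id"]]) if "id" in cols and not pd.isna(row[cols["id"]]) else f"site{i:04d}"
            start = int(row[cols["start"]])
            if kind is IndelKind.DEL:
                sites.append(IndelSite.deletion(str(row[cols["chrom"]]), start - 1, int(row[cols["end"]]), id=rid))
            else:
                length = int(row[cols["length"]]) if "length" in cols else None
                if not length:
                    raise ValueError("insertion row without length")
                sites.append(IndelSite.insertion(str(row[cols["chrom"]]), start - 1, length, id=rid))
        except (ValueError, KeyError) as exc:
            skipped += 1
            logger.info("skipping site row %d (%s)", i, exc)
    return sites, skipped


def read_sites(path: str, format: str | None = None) -> SiteTable:
    """Load indel sites from VCF (SVTYPE/END/SVLEN) or TSV.

    Records that cannot be interpreted are skipped with a logged reason and
    counted in ``n_skipped``; a file yielding no valid sites is an error.
    """
    if format is None:
        format = "VCF" if path.endswith((".vcf", ".vcf.gz", ".bcf")) else "TSV"
    if format.upper() == "VCF":
        sites, skipped = _sites_from_vcf(path)
    else:
        sites, skipped = _sites_from_tsv(path)
    if not sites:
        raise ValueError(f"no valid indel sites in {path}")
    if skipped:
        logger.info("%d site records skipped in %s", skipped, path)
    return SiteTable(sites, source=path, n_skipped=skipped)


def write_sites_tsv(sites: Iterable[IndelSite], path: str) -> None:
    rows = []
    for s in sites:
        rows.append(
            {
                "chrom": s.chrom,
                "start": s.p1 + 1,
                "end": s.p2 if s.kind is IndelKind.DEL else s.p1,
                "kind": s.kind.value,
                "id": s.label,
                "length": s.length,
            }
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Run configuration
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Everything that determines a run; serializable and digest-stamped."""

    evidence: EvidenceConfig = field(default_factory=EvidenceConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    seed: int = 0
    mu: float | None = None
    sigma: float | None = None
    extra: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "evidence": dataclasses.asdict(self.evidence),
            "sim": dataclasses.asdict(self.sim),
            "seed": self.seed,
            "mu": self.mu,
            "sigma": self.sigma,
            "extra": self.extra,
        }

    @classmethod
    def from_dict(cls, payload: dict) -> "RunConfig":
        return cls(
            evidence=EvidenceConfig(**payload["evidence"]),
            sim=SimConfig(**{**payload["sim"], "genotype_freqs": tuple(payload["sim"]["genotype_freqs"])}),
            seed=payload["seed"],
            mu=payload.get("mu"),
            sigma=payload.get("sigma"),
            extra=payload.get("extra", {}),
        )

    def digest(self) -> str:
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# Genotype VCF output
# ---------------------------------------------------------------------------

_GT_MAP = {0: "0/0", 1: "0/1", 2: "1/1"}


def write_genotype_vcf(
    calls: Sequence[GenotypeCall],
    sites: Sequence[IndelSite],
    samples: Sequence[str],
    path: str,
    with_probs: bool = False,
    config: RunConfig | None = None,
) -> None:
    """One record per site; FORMAT GT (0/0, 0/1, 1/1) and optionally GP.

    Calls must reference known (sample, site) combinations; the header
    records the tool version and the run-config digest.
    """
    by_label = {s.label: s for s in sites}
    table: dict[str, dict[str, GenotypeCall]] = {}
    for call in calls:
        if call.site_id not in by_label:
            raise ValueError(f"call references unknown site {call.site_id!r}")
        if call.sample not in samples:
            raise ValueError(f"call references unknown sample {call.sample!r}")
        table.setdefault(call.site_id, {})[call.sample] = call

    lines = [
        "##fileformat=VCFv4.2",
        f"##source=indelgt-{__version__}",
        *(f"##contig=<ID={chrom}>" for chrom in sorted({s.chrom for s in sites})),
        '##INFO=<ID=SVTYPE,Number=1,Type=String,Description="Type of structural variant">',
        '##INFO=<ID=END,Number=1,Type=Integer,Description="End position of the variant">',
        '##INFO=<ID=SVLEN,Number=1,Type=Integer,Description="Length of the variant">',
        '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">',
    ]
    if with_probs:
        lines.append(
            '##FORMAT=<ID=GP,Number=G,Type=Float,Description="Genotype probabilities for 0/0, 0/1, 1/1">'
        )
    if config is not None:
        lines.append(f"##indelgt_config_digest={config.digest()}")
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t" + "\t".join(samples))

    fmt = "GT:GP" if with_probs else "GT"
    for site in sorted(sites, key=lambda s: (s.chrom, s.p1)):
        if site.kind is IndelKind.DEL:
            info = f"SVTYPE=DEL;END={site.p2};SVLEN=-{site.length}"
            alt = "<DEL>"
        else:
            info = f"SVTYPE=INS;SVLEN={site.length}"
            alt = "<INS>"
        cells = []
        for sample in samples:
            call = table.get(site.label, {}).get(sample)
            if call is None:
                cells.append("./." + (":.,.,." if with_probs else ""))
            elif with_probs:
                probs = call.probs or (0.0, 0.0, 0.0)
                cells.append(_GT_MAP[call.g] + ":" + ",".join(f"{p:.4f}" for p in probs))
            else:
                cells.append(_GT_MAP[call.g])
        lines.append(
            "\t".join(
                [
                    site.chrom,
                    str(site.p1 + 1),
                    site.label,
                    "N",
                    alt,
                    ".",
                    "PASS",
                    info,
                    fmt,
                    *cells,
                ]
            )
        )
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
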