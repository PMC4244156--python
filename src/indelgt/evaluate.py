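"""Scoring genotype calls: stratified accuracy, trio concordance, downsampling.

Accuracy is the fraction of (individual, site) genotypes called identically
to truth, reported per length or per carrier-frequency stratum.  Trio
metrics flag Mendelian-impossible father/mother/child triples and all-zero
triples; downsampling metrics count genotypes that change when a random
fraction of read pairs is removed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Hashable, Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import pysam

from .evidence import IndelKind, IndelSite

logger = logging.getLogger("indelgt")

__all__ = [
    "DEFAULT_LENGTH_BINS",
    "MENDELIAN_DISCORDANT_TRIPLES",
    "AccuracyTable",
    "TrioMetrics",
    "length_stratum",
    "frequency_stratum",
    "stratified_accuracy",
    "is_mendelian_discordant",
    "trio_discordance",
    "downsample_templates",
    "downsample_bam",
    "changed_genotypes",
]

#: Length strata of the accuracy reports (bp, lower inclusive / upper exclusive).
DEFAULT_LENGTH_BINS: tuple[tuple[int, float], ...] = (
    (50, 200),
    (200, 400),
    (400, 500),
    (500, 1500),
    (1500, float("inf")),
)

#: The eight Mendelian-impossible trio genotype triples, parents unordered
#: (sorted ascending), third entry the child.
MENDELIAN_DISCORDANT_TRIPLES: frozenset[tuple[int, int, int]] = frozenset(
    {
        (0, 0, 1),
        (0, 0, 2),
        (0, 1, 2),
        (0, 2, 0),
        (0, 2, 2),
        (1, 2, 0),
        (2, 2, 0),
        (2, 2, 1),
    }
)


@dataclass
class AccuracyTable:
    """Per-stratum genotype accuracy with an overall row."""

    table: pd.DataFrame  # columns: stratum, n_sites, n_genotypes, accuracy

    @property
    def overall(self) -> float:
        return float(self.table.loc[self.table["stratum"] == "overall", "accuracy"].iloc[0])

    def stratum(self, label: str) -> float:
        row = self.table.loc[self.table["stratum"] == label, "accuracy"]
        if row.empty:
            raise KeyError(label)
        return float(row.iloc[0])


@dataclass
class TrioMetrics:
    n_discordant: int
    n_all_zero: int
    n_sites: int
    n_missing: int = 0

    def __post_init__(self) -> None:
        if self.n_discordant > self.n_sites or self.n_all_zero > self.n_sites:
            raise ValueError("counts exceed the number of scored sites")


def length_stratum(site: IndelSite, bins: Sequence[tuple[int, float]] = DEFAULT_LENGTH_BINS) -> str:
    for lo, hi in bins:
        if lo <= site.length < hi:
            return f"{lo}–{hi:g}" if np.isfinite(hi) else f">{lo}"
    return "other"


def frequency_stratum(carrier_count: int, bins: Sequence[tuple[int, int]] = ((0, 5), (6, 15), (16, 30), (31, 45))) -> str:
    for lo, hi in bins:
        if lo <= carrier_count <= hi:
            return f"{lo}–{hi}"
    return "other"


def _as_call_frame(calls: "pd.DataFrame | Iterable") -> pd.DataFrame:
    if isinstance(calls, pd.DataFrame):
        return calls[["sample", "site_id", "g"]].copy()
    rows = [{"sample": c.sample, "site_id": c.site_id, "g": c.g} for c in calls]
    return pd.DataFrame(rows)


def stratified_accuracy(
    calls: "pd.DataFrame | Iterable",
    truth: pd.DataFrame,
    strata: Mapping[str, str] | None = None,
) -> AccuracyTable:
    """Fraction of correctly called genotypes, overall and per stratum.

    ``truth`` needs columns sample, site_id, g; ``strata`` maps site_id to a
    stratum label (length bin, frequency bin, ...).  The call and truth key
    sets must match exactly — orphans on either side are an error.
    """
    calls_df = _as_call_frame(calls)
    truth_df = truth[["sample", "site_id", "g"]]
    merged = calls_df.merge(truth_df, on=["sample", "site_id"], how="outer",
                            suffixes=("_call", "_true"), indicator=True)
    orphans = merged[merged["_merge"] != "both"]
    if not orphans.empty:
        keys = list(orphans[["sample", "site_id"]].itertuples(index=False, name=None))[:5]
        raise ValueError(f"calls and truth keys mismatch, e.g. {keys}")
    merged["correct"] = merged["g_call"] == merged["g_true"]
    merged["stratum"] = (
        merged["site_id"].map(strata).fillna("other") if strata is not None else "overall"
    )

    rows = []
    groups = [("overall", merged)]
    if strata is not None:
        labels = pd.unique(pd.Series(list(strata.values())))
        for label in labels:
            groups.append((label, merged[merged["stratum"] == label]))
    for label, grp in groups:
        n_genotypes = len(grp)
        rows.append(
            {
                "stratum": label,
                "n_sites": grp["site_id"].nunique(),
                "n_genotypes": n_genotypes,
                "accuracy": float(grp["correct"].mean()) if n_genotypes else float("nan"),
            }
        )
    return AccuracyTable(pd.DataFrame(rows))


def is_mendelian_discordant(father: int, mother: int, child: int) -> bool:
    """True iff the triple is impossible under biallelic inheritance."""
    for g in (father, mother, child):
        if g not in (0, 1, 2):
            raise ValueError(f"malformed genotype {g!r}")
    p1, p2 = sorted((father, mother))
    return (p1, p2, child) in MENDELIAN_DISCORDANT_TRIPLES


def trio_discordance(
    triples: Iterable[tuple[int | None, int | None, int | None]]
) -> TrioMetrics:
    """Count Mendelian-impossible and all-zero (father, mother, child) triples.

    Triples with a missing genotype (None) are excluded from both counts and
    tallied separately.
    """
    n_disc = n_zero = n_sites = n_missing = 0
    for father, mother, child in triples:
        if father is None or mother is None or child is None:
            n_missing += 1
            continue
        n_sites += 1
        if is_mendelian_discordant(father, mother, child):
            n_disc += 1
        if (father, mother, child) == (0, 0, 0):
            n_zero += 1
    return TrioMetrics(n_disc, n_zero, n_sites, n_missing)


def downsample_templates(
    names: Sequence[Hashable], fraction: float, seed: int
) -> set[Hashable]:
    """Keep each template independently with probability ``fraction``.

    Deterministic given the seed and the set of names (order-insensitive:
    names are sorted before drawing).
    """
    if not 0 <= fraction <= 1:
        raise ValueError("fraction must be in [0, 1]")
    rng = np.random.default_rng(seed)
    unique = sorted(set(names))
    keep = rng.random(len(unique)) < fraction
    return {name for name, k in zip(unique, keep) if k}


def downsample_bam(in_path: str, out_path: str, fraction: float, seed: int) -> str:
    """Random read-fraction keeping: pairs are kept or dropped atomically."""
    with pysam.AlignmentFile(in_path) as src:
        names = {rec.query_name for rec in src.fetch(until_eof=True)}
    kept = downsample_templates(sorted(names), fraction, seed)
    with pysam.AlignmentFile(in_path) as src:
        with pysam.AlignmentFile(out_path, "wb", template=src) as dst:
            for rec in src.fetch(until_eof=True):
                if rec.query_name in kept:
                    dst.write(rec)
    pysam.index(out_path)
    return out_path


def changed_genotypes(
    full_calls: Mapping[Hashable, int], reduced_calls: Mapping[Hashable, int]
) -> tuple[int, int]:
    """(changed, denominator) between full-coverage and downsampled calls.

    A genotype counts as changed when the reduced call differs from the full
    call or is absent; the denominator is the full-call universe.
    """
    changed = sum(
        1 for key, g in full_calls.items() if reduced_calls.get(key) != g
    )
    return changed, len(full_calls)
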