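"""End-to-end experiment workflows: simulate -> extract -> train -> score.

These functions wire the modules together for the canonical synthetic
experiments: a deletion cohort with per-site allele frequencies, repeated
train/test rounds with held-out individuals, feature-ablation comparisons,
read-duplication normalization checks and downsampling consistency.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
import pysam

from .evidence import EvidenceConfig, IndelSite, LibraryStats
from .evaluate import changed_genotypes, downsample_bam, length_stratum, stratified_accuracy
from .features import FEATURE_COLUMNS, extract_feature_table
from .genotyper import (
    DEFAULT_C_GRID,
    DEFAULT_GAMMA_GRID,
    GenotypeModel,
    call_genotypes,
    train_genotyper,
)
from .simulate import SimConfig, TruthMatrix, assign_truth_genotypes, random_deletion_sites, random_reference, simulate_individual_bam

__all__ = [
    "DeletionCohort",
    "simulate_deletion_cohort",
    "heldout_accuracy_rounds",
    "ablation_cv_accuracies",
    "duplicate_bam_templates",
    "normalization_shift_on_duplication",
    "downsampling_consistency",
]


@dataclass
class DeletionCohort:
    """A simulated deletion cohort with extracted, labeled features."""

    ref: str
    sites: list[IndelSite]
    truth: TruthMatrix
    cfg: SimConfig
    lib: LibraryStats
    evidence_cfg: EvidenceConfig
    bam_paths: dict[str, str]
    features: pd.DataFrame
    allele_freqs: np.ndarray


def simulate_deletion_cohort(
    outdir: str,
    seed: int,
    n_sites: int = 60,
    ref_len: int = 1_000_000,
    n_individuals: int = 20,
    coverage: float = 6.0,
    af_range: tuple[float, float] = (0.0, 0.5),
    min_len: int = 50,
    max_len: int = 5000,
) -> DeletionCohort:
    """Simulate a diploid deletion cohort and extract its feature table.

    Deletion lengths are log-uniform in [min_len, max_len]; per-site allele
    frequencies are uniform in ``af_range`` with Hardy-Weinberg genotypes;
    reads are placed at their true origins (ideal alignment).
    """
    rng = np.random.default_rng(seed)
    cfg = SimConfig(coverage=coverage, n_individuals=n_individuals, seed=seed)
    ecfg = EvidenceConfig()
    lib = LibraryStats(mu=cfg.insert_mean, sigma=cfg.insert_sd, read_len=cfg.read_len)
    ref = random_reference(ref_len, rng)
    sites = random_deletion_sites(n_sites, ref_len, rng, min_len=min_len, max_len=max_len)
    allele_freqs = rng.uniform(*af_range, size=n_sites)
    truth = assign_truth_genotypes(sites, cfg, rng, allele_freqs=allele_freqs)

    os.makedirs(outdir, exist_ok=True)
    bam_paths: dict[str, str] = {}
    tables = []
    for i, ind in enumerate(truth.individuals):
        path = os.path.join(outdir, f"{ind}.bam")
        simulate_individual_bam(
            path, ref, sites, truth.genotypes[i], truth.hap_choice[i], cfg, rng, sample=ind
        )
        bam_paths[ind] = path
        tables.append(
            extract_feature_table(path, sites, lib=lib, cfg=ecfg, sample=ind,
                                  labels=truth.genotypes[i])
        )
    features = pd.concat(tables, ignore_index=True)
    return DeletionCohort(ref, sites, truth, cfg, lib, ecfg, bam_paths, features, allele_freqs)


def _train_on(
    features: pd.DataFrame,
    seed: int,
    columns: Sequence[str] = FEATURE_COLUMNS,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> GenotypeModel:
    return train_genotyper(
        features[list(columns)].to_numpy(),
        features["label"].to_numpy(),
        seed=seed,
        c_grid=c_grid,
        gamma_grid=gamma_grid,
        feature_names=columns,
    )


def heldout_accuracy_rounds(
    cohort: DeletionCohort,
    n_rounds: int = 10,
    n_test: int = 5,
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
) -> pd.DataFrame:
    """Repeated random train/test splits over individuals.

    Per round, ``n_test`` individuals are held out, a model is trained on
    the rest and the held-out genotype accuracy is computed overall and per
    length stratum.  Returns one row per round.
    """
    strata = {s.label: length_stratum(s) for s in cohort.sites}
    inds = np.array(cohort.truth.individuals)
    rng = np.random.default_rng(seed)
    rows = []
    for rnd in range(n_rounds):
        test = set(rng.choice(inds, size=n_test, replace=False))
        train_df = cohort.features[~cohort.features["sample"].isin(test)]
        test_df = cohort.features[cohort.features["sample"].isin(test)]
        model = _train_on(train_df, seed=seed + rnd, c_grid=c_grid, gamma_grid=gamma_grid)
        calls = call_genotypes(
            model,
            test_df[list(FEATURE_COLUMNS)].to_numpy(),
            samples=test_df["sample"].tolist(),
            site_ids=test_df["site_id"].tolist(),
        )
        truth_df = test_df[["sample", "site_id", "label"]].rename(columns={"label": "g"})
        table = stratified_accuracy(calls, truth_df, strata=strata)
        row = {"round": rnd, "cv_accuracy": model.cv_accuracy, "overall": table.overall}
        for label in set(strata.values()):
            try:
                row[label] = table.stratum(label)
            except KeyError:
                row[label] = float("nan")
        rows.append(row)
    return pd.DataFrame(rows)


#: Feature-subset definitions for the deletion ablation, by column index:
#: pairs = discordant+concordant, spans = split+full, depth alone.
ABLATION_SUBSETS: dict[str, tuple[str, ...]] = {
    "all": ("f1", "f2", "f3", "f4", "f5"),
    "pairs": ("f1", "f2"),
    "spans": ("f3", "f4"),
    "depth": ("f5",),
}


def ablation_cv_accuracies(
    cohort: DeletionCohort,
    seed: int = 0,
    c_grid: Sequence[float] = DEFAULT_C_GRID,
    gamma_grid: Sequence[float] = DEFAULT_GAMMA_GRID,
    subsets: dict[str, tuple[str, ...]] | None = None,
) -> dict[str, float]:
    """Cross-validated accuracy per feature subset on the same training data."""
    subsets = subsets or ABLATION_SUBSETS
    out = {}
    for name, columns in subsets.items():
        model = _train_on(cohort.features, seed=seed, columns=columns,
                          c_grid=c_grid, gamma_grid=gamma_grid)
        out[name] = model.cv_accuracy
    return out


def duplicate_bam_templates(in_path: str, out_path: str) -> str:
    """Write every record twice (the copy under a new template name).

    Doubles every evidence count and the local coverage, which must leave
    normalized features essentially unchanged.
    """
    with pysam.AlignmentFile(in_path) as src:
        with pysam.AlignmentFile(out_path, "wb", template=src) as dst:
            for rec in src.fetch(until_eof=True):
                dst.write(rec)
                dup = pysam.AlignedSegment.fromstring(rec.to_string(), rec.header)
                dup.query_name = rec.query_name + "_dup"
                dst.write(dup)
    pysam.index(out_path)
    return out_path


def normalization_shift_on_duplication(
    cohort: DeletionCohort, individual: str, workdir: str
) -> pd.DataFrame:
    """Per-site relative change of each normalized feature after read doubling."""
    src = cohort.bam_paths[individual]
    dup = os.path.join(workdir, f"{individual}.dup.bam")
    duplicate_bam_templates(src, dup)
    base = extract_feature_table(src, cohort.sites, lib=cohort.lib,
                                 cfg=cohort.evidence_cfg, sample=individual)
    doubled = extract_feature_table(dup, cohort.sites, lib=cohort.lib,
                                    cfg=cohort.evidence_cfg, sample=individual)
    a = base[list(FEATURE_COLUMNS)].to_numpy()
    b = doubled[list(FEATURE_COLUMNS)].to_numpy()
    denom = np.where(a > 0, a, 1.0)  # relative change; exact zeros compared absolutely
    rel = np.abs(b - a) / denom
    return pd.DataFrame(rel, columns=FEATURE_COLUMNS, index=base["site_id"])


def downsampling_consistency(
    cohort: DeletionCohort,
    workdir: str,
    seed: int,
    coverage: float = 12.0,
    fraction: float = 0.25,
    n_test: int = 5,
) -> tuple[int, int]:
    """Changed genotypes between full-coverage and downsampled calls.

    Fresh individuals are simulated at ``coverage`` on the cohort's
    reference and sites, genotyped with a model trained on the cohort, then
    re-genotyped after randomly keeping ``fraction`` of the read pairs.
    Returns (n_changed, n_total).
    """
    rng = np.random.default_rng(seed)
    model = _train_on(cohort.features, seed=seed)
    cfg = SimConfig(coverage=coverage, n_individuals=n_test, seed=seed)
    truth = assign_truth_genotypes(
        cohort.sites, cfg, rng, allele_freqs=cohort.allele_freqs,
        individuals=[f"ds{i:02d}" for i in range(n_test)],
    )
    os.makedirs(workdir, exist_ok=True)
    full_calls: dict[tuple[str, str], int] = {}
    reduced_calls: dict[tuple[str, str], int] = {}
    for i, ind in enumerate(truth.individuals):
        full_bam = os.path.join(workdir, f"{ind}.full.bam")
        simulate_individual_bam(full_bam, cohort.ref, cohort.sites, truth.genotypes[i],
                                truth.hap_choice[i], cfg, rng, sample=ind)
        ds_bam = os.path.join(workdir, f"{ind}.ds.bam")
        downsample_bam(full_bam, ds_bam, fraction, seed=seed + i)
        for calls, bam in ((full_calls, full_bam), (reduced_calls, ds_bam)):
            table = extract_feature_table(bam, cohort.sites, lib=cohort.lib,
                                          cfg=cohort.evidence_cfg, sample=ind)
            got = call_genotypes(
                model,
                table[list(FEATURE_COLUMNS)].to_numpy(),
                samples=table["sample"].tolist(),
                site_ids=table["site_id"].tolist(),
            )
            calls.update({(c.sample, c.site_id): c.g for c in got})
    return changed_genotypes(full_calls, reduced_calls)
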