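"""Shared fixtures: a crafted-record BAM builder and a small simulated cohort."""

from __future__ import annotations

import os

import numpy as np
import pandas as pd
import pysam
import pytest

from indelgt import SimConfig, assign_truth_genotypes, random_deletion_sites, random_reference
from indelgt.features import extract_feature_table
from indelgt.simulate import simulate_individual_bam


def make_bam(path, specs, ref_name="chr1", ref_len=20_000):
    """Write an indexed BAM from a list of record dicts.

    Each spec: qname, pos, cigar (string), and optional flags/mate fields.
    Defaults describe a well-mapped left mate of an FR pair.
    """
    header = pysam.AlignmentHeader.from_dict(
        {"HD": {"VN": "1.6", "SO": "coordinate"}, "SQ": [{"SN": ref_name, "LN": ref_len}]}
    )
    records = []
    for spec in specs:
        rec = pysam.AlignedSegment(header)
        rec.query_name = spec["qname"]
        rec.reference_id = 0
        rec.reference_start = spec["pos"]
        rec.cigarstring = spec.get("cigar", "100M")
        rec.mapping_quality = spec.get("mapq", 60)
        rec.is_paired = True
        rec.is_read1 = spec.get("read1", True)
        rec.is_read2 = not rec.is_read1
        rec.is_reverse = spec.get("reverse", False)
        rec.mate_is_reverse = spec.get("mate_reverse", not rec.is_reverse)
        rec.is_supplementary = spec.get("supplementary", False)
        rec.is_unmapped = spec.get("unmapped", False)
        rec.mate_is_unmapped = spec.get("mate_unmapped", False)
        rec.next_reference_id = 0
        rec.next_reference_start = spec.get("mate_pos", spec["pos"])
        rec.template_length = spec.get("tlen", 0)
        records.append(rec)
    records.sort(key=lambda r: r.reference_start)
    with pysam.AlignmentFile(path, "wb", header=header) as out:
        for rec in records:
            out.write(rec)
    pysam.index(str(path))
    return str(path)


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """Six diploid individuals, 12 deletions on a 200 kb reference at 10x.

    Genotypes are drawn uniformly over 0/1/2 so every class is populated;
    feature tables carry the truth genotype in the `label` column.
    """
    rng = np.random.default_rng(20240)
    ref_len = 200_000
    ref = random_reference(ref_len, rng)
    sites = random_deletion_sites(12, ref_len, rng)
    cfg = SimConfig(coverage=10.0, n_individuals=6, seed=20240,
                    genotype_freqs=(1 / 3, 1 / 3, 1 / 3))
    truth = assign_truth_genotypes(sites, cfg, rng)
    outdir = tmp_path_factory.mktemp("small_cohort")
    bam_paths = {}
    tables = []
    for i, ind in enumerate(truth.individuals):
        path = os.path.join(outdir, f"{ind}.bam")
        simulate_individual_bam(
            path, ref, sites, truth.genotypes[i], truth.hap_choice[i],
            cfg, rng, sample=ind,
        )
        bam_paths[ind] = path
        tables.append(
            extract_feature_table(path, sites, sample=ind, labels=truth.genotypes[i])
        )
    return {
        "ref": ref,
        "sites": sites,
        "cfg": cfg,
        "truth": truth,
        "bam_paths": bam_paths,
        "features": pd.concat(tables, ignore_index=True),
    }
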