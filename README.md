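# indelgt

Genotype calling for large (≥ 50 bp) insertions and deletions from
paired-end sequencing data.

## The problem

Structural-variant discovery tools report *where* an indel is; population
genetics needs to know *who carries it, and in how many copies*. For a
diploid individual each indel site has genotype 0 (homozygous reference), 1
(heterozygous) or 2 (homozygous indel). Calling that genotype from low
coverage whole-genome sequencing is hard: any single read signature
(a discordant insert size, a clipped read, a dip in depth) is noisy and
often absent at 4–10×.

`indelgt` combines **five** read-evidence signatures per (individual, site)
and lets a support-vector machine learn how to weigh them:

| evidence | deletion | insertion | supports |
|---|---|---|---|
| discordant encompassing pairs, insert ≈ μ + L (DEL) / μ − L (INS) | ✓ | ✓ | indel allele |
| concordant encompassing pairs, insert ≈ μ | ✓ | ✓ | reference allele |
| split reads (two segments clipped at both breakpoints) | ✓ | – | indel allele |
| soft-clipped (partially mapped) reads at a breakpoint | – | ✓ | indel allele |
| fully mapped reads spanning a breakpoint | ✓ | ✓ | reference allele |
| single-end-mapped pairs (mate unmapped) | – | ✓ | long-insertion allele |
| mean read depth over the deleted interval | ✓ | – | dosage |

Counts are normalized by the *local coverage* λ (mean depth of the two
breakpoint-flanking windows of width μ + 3σ), so an individual sequenced at
4× and one at 30× map to the same feature space. Each (individual, site) is
then a point **x** ∈ ℝ⁵; deletion features are ordered
(discordant, concordant, split, full, depth). An RBF-kernel SVM with
min-max scaling to [−1, 1], (C, γ) grid search and stratified 10-fold
cross-validation separates the three genotype classes; the per-class
probabilities (Platt pairwise coupling) are available with `-b`.

Because validated training genotypes are rare, the package ships a diploid
read simulator: planted indels with known genotypes (heterozygotes get the
event on one arbitrary haplotype), Normal(500, 50) insert sizes, 100 bp
reads, 2% base error, and either paired FASTQ or ideal "truth placement"
alignments with split/soft-clipped records at the junctions. The evaluation
module scores calls with length- and frequency-stratified accuracy, trio
Mendelian-discordance counts (the eight impossible father/mother/child
triples), all-zero trio counts, and changed-genotype counts under random
read downsampling.

## Worked example

Simulate six individuals over a 300 kb reference with 12 planted deletions
at 8×, extract features, train on four individuals and genotype the other
two:

```sh
indelgt simulate --out-prefix sim --ref-length 300000 --n-sites 12 \
    --n-individuals 6 --coverage 8 --seed 42
for i in 00 01 02 03 04 05; do
  indelgt extract-features sim.ind$i.bam sim.sites.tsv \
      --out ind$i.features.tsv --sample ind$i --mu 500 --sigma 50
done
# train.features.tsv = ind00..03, test.features.tsv = ind04..05
indelgt train train.features.tsv --truth sim.truth.tsv --out model.json --seed 1
indelgt genotype test.features.tsv --model model.json \
    --sites sim.sites.tsv --out calls.vcf -b
indelgt evaluate calls.tsv --truth test.truth.tsv
```

which prints

```
model written to model.json (CV accuracy 1.0000, C=2^1, gamma=2^-1)
wrote 24 genotype calls to calls.vcf
stratum  n_sites  n_genotypes  accuracy
overall       12           24       1.0
overall accuracy: 1.0000
```

The training step reports the cross-validated accuracy of the selected
(C, γ) grid point; `calls.vcf` has one record per site with per-sample
`GT` (0/0, 0/1, 1/1) and, with `-b`, a `GP` field holding the three
genotype probabilities. The final line is the fraction of held-out
genotypes that match the simulated truth — on this small, clean cohort the
classifier is exact; at lower coverage and shorter deletions accuracy
drops into the 0.90–0.99 range (see the reproduction script below).

Real data enters the same way: a coordinate-sorted, indexed BAM per
individual and a site list (VCF with `SVTYPE` + `END`/`SVLEN`, or a TSV
with chrom/start/end/kind). Insert-size statistics are estimated from the
BAM when `--mu/--sigma` are not given.

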