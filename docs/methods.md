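# Methods

## Model

Each known indel site is described by breakpoints p1 ≤ p2 on the reference
(0-based internally; p1 is the first deleted base and p2 one past the last;
insertions have p1 = p2 and an inserted length L). Around each site, reads
are fetched from the window [p1 − D, p2 + D] with D = μ + nσ·σ, where μ and
σ are the library insert-size mean and standard deviation and nσ = 3: a
read can belong to an indel-overlapping pair only if it starts within one
maximal insert of a breakpoint.

A read pair (both mates mapped, forward–reverse orientation) whose outer
span covers a breakpoint is classified by its template length T:

- **discordant support** — |T − μ − L_adj| ≤ nσ·σ with L_adj = +L for
  deletions and −L for insertions, and the two mates on opposite sides of
  the event;
- **concordant** — |T − μ| ≤ nσ·σ;
- **invalid** — T > max(μ, μ + L_adj) + nσ·σ: likely mismapped, discarded;
- otherwise uninformative.

For events short enough that the two insert windows overlap, the pair goes
to the nearer window centre; exact ties resolve to concordant (the
conservative reading). A pair with exactly one mapped mate is evidence only
at insertion sites (a mate inside a long insertion cannot map). Pairs with
both mates unmapped or both below MAPQ 20 are dropped; multi-aligned
templates are deduplicated by read name so each physical pair contributes
once per site.

Reads overlapping a breakpoint are classified from their clip structure,
with a slack c (default 15 bp) between clip boundaries and breakpoints
because discovery tools rarely report exact breakpoints:

- **split** (deletions only) — two mapped segments whose inner edges fall
  within c of p1 and p2;
- **partial** — a soft clip of at least `min_clip` (5 bp) whose boundary is
  within c of a breakpoint;
- **full** — an end-to-end segment (clips ≤ c) strictly covering a
  breakpoint with ≥ 1 aligned base on each side.

Precedence split > partial > full keeps the classes disjoint. Clips
shorter than `min_clip` are treated as alignment noise: real aligners
produce small terminal clips from sequencing error, and counting them as
breakpoint evidence would swamp the partial-read feature.

## Features and normalization

Deletion vectors are (discordant, concordant, split, full, depth); the
depth component is the mean aligned-base coverage over [p1, p2).
Insertion vectors are (discordant, concordant, single-end-mapped, partial,
full); interval depth is undefined for an insertion, and the applicability
of pair features for short versus long insertions is left to the
classifier rather than hard-switched on a length threshold.

Every component is divided by the local coverage λ, the mean of the mean
depths of [p1 − w, p1) and [p2, p2 + w) with w = μ + 3σ (the same locality
the pair evidence sees). Normalizing the depth component too makes the
vector scale-free: homozygous-reference deletion sites sit near 1.0 in the
depth coordinate at any sequencing depth. When λ < 0.5× (a near-empty
region) the sample-wide mean coverage substitutes for λ so vectors stay
finite; at a contig edge the surviving flank alone defines λ. Depth counts
only aligned (CIGAR M/=/X) bases — soft clips and spliced gaps do not
contribute.

## Classification

Features are min-max scaled to [−1, 1] per dimension (constant training
columns map to 0; out-of-range inputs extrapolate linearly). An RBF-kernel
SVM is selected over the canonical coarse grid C ∈ {2⁻⁵, 2⁻³, …, 2¹⁵},
γ ∈ {2⁻¹⁵, 2⁻¹³, …, 2³} by stratified 10-fold cross-validated accuracy
(folds shuffle under the run seed; classes with fewer members than folds
reduce the fold count with a warning). Ties prefer smaller C, then smaller
γ — the smoother model. The winner is refit on all training data.
Separate models are trained per indel kind, since the five components mean
different things for deletions and insertions. Optional inverse-frequency
class weights are available for heavily imbalanced cohorts (genotype 0
dominates at low allele frequency) but are off by default.

When probabilities are requested the reported genotype is the argmax of
the three-class pairwise-coupling probabilities (ties to the smaller
genotype), so the call and its probabilities are consistent by
construction.

Models persist as a single self-describing JSON file holding the scaler
ranges, the winning (C, γ), the class set, the feature order and the
scaled training matrix; loading refits deterministically, reproducing
predictions bit-for-bit. A feature-order mismatch at load time is a hard
error — silently permuting features is the worst failure mode a genotyper
can have.

## Simulator

The simulator emulates low-coverage population sequencing of diploid
individuals with planted indels. Defaults: 100 bp reads, insert
Normal(500, 50) truncated below at 2·read_len, 2% uniform substitution
error, genotype frequencies (0.7, 0.2, 0.1) for wild-type/het/hom; per-site
allele frequencies with Hardy–Weinberg draws are supported for population
experiments. Heterozygous carriers get the event on one seed-chosen
haplotype. Round(c·G / 2l) fragment pairs per individual are split
binomially between haplotypes. The insert-size SD is not a quantity the
defaults can inherit from the study conditions (only the mean of 500 is
fixed there), so 50 (10% of the mean) is used and exposed as a knob.

Output is either paired FASTQ (mate 2 reverse-complemented) for an
external aligner, or **truth placements**: a coordinate-sorted BAM built
directly from the known fragment origins through the haplotype→reference
block liftover. A read crossing a deletion junction becomes a primary
alignment (longer side matched, other side soft-clipped) plus a
supplementary record when the other side is ≥ 20 bp — the representation a
soft-clipping mapper produces for large deletions. Read portions inside
inserted sequence are soft-clipped; reads entirely inside an insertion are
unmapped (single-end-mapped pairs). Truth-placement records omit SEQ
because evidence extraction never inspects base content.

What the simulator does **not** model: quality-score profiles, indel
sequencing errors, PCR duplicates, GC and mappability bias, repeats, and
mapping ambiguity (truth placements are ideal alignments with MAPQ 60).
Passing tests on this data therefore demonstrates the correctness of the
evidence → feature → classifier → metrics chain under clean mapping, not
robustness to alignment artifacts on real genomes; with real data the
package consumes whatever a soft-clipping aligner produced, and the MAPQ
filter plus the invalid-pair cap are the only defenses against mismapping.

Trio mode draws parents i.i.d. and gives the child one allele from each
parent, making truth trios Mendelian-consistent by construction — the
zero-baseline for the discordance metric.

## Evaluation

Accuracy is the fraction of (individual, site) calls equal to truth,
reported overall and per stratum (length bins 50–200, 200–400, 400–500,
500–1500, > 1500 bp; frequency bins 0–5, 6–15, 16–30, 31–45 carriers,
computed from truth genotypes). A trio is discordant iff its
unordered-parents triple is one of the eight Mendelian-impossible cases
{(0,0,1), (0,0,2), (0,1,2), (0,2,0), (0,2,2), (1,2,0), (2,2,0), (2,2,1)};
the test suite verifies this set against a brute-force enumeration of
parental allele donations. Downsampling keeps each template independently
with probability f (pairs atomic, order-insensitive and
seed-deterministic); a genotype counts as changed when the reduced call
differs from the full call or is missing.

## Canonical synthetic experiment

The reproduction script and the heavier tests use one cohort: a 1 Mbp
i.i.d. random reference, 60 non-overlapping deletions with log-uniform
lengths in [50, 5000] bp and ≥ 2 kb spacing (so flanking windows do not
touch neighbouring events), 20 individuals with per-site allele frequency
uniform on (0, 0.5), truth-placement alignments at 6×, and ten rounds of
15-train/5-test splits. These sizes were chosen as the smallest population
in which all length strata and all three genotype classes are well
populated; the 2 kb spacing and the random reference are the main
departures from real genomes (real indels cluster and real sequence
repeats). Downsampling consistency trains on that cohort and compares
calls on five fresh individuals at 12× against the same read sets thinned
to 25%.

## Numerical choices and degenerate inputs

- Insert statistics: sample standard deviation (ddof = 1) after Tukey
  3×IQR fencing; the modal read length; at least 100 proper pairs or an
  explicit μ/σ is required.
- Windows clip at contig boundaries; fetch regions clip at the reference
  length.
- A site on a contig absent from the BAM header scores all-zero counts
  with a warning rather than aborting a cohort run.
- Empty regions are errors for depth means; λ = 0 triggers the documented
  fallback.
- Genotype-frequency vectors must sum to 1 within 1e-9.
- Seeds: every stochastic step (truth draws, fragment sampling, fold
  shuffling, downsampling) takes an explicit seed or generator; repeated
  runs are bit-identical.

## Known limitations

- Breakpoint accuracy matters for the split/partial features; the slack c
  absorbs ±15 bp but grossly wrong breakpoints degrade to depth+pair
  evidence only.
- Insertions longer than the insert size rely on single-end-mapped and
  clipped reads alone; genotype 1 vs 2 separation is weaker there.
- The depth feature is uncorrected for GC and mappability, which is
  visible on real data as inflated variance of the depth coordinate.
- Overlapping indel sites are rejected by the simulator and not treated
  specially by the extractor (each site is scored independently).
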