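# Methods

This note records the models behind `tetrasnp`, the parameters that matter,
the choices made where the design was genuinely open, and what the passing
tests do and do not demonstrate about real data.

## Subgenome model

Both subgenomes descend from one simulated ancestral sequence and are
strictly **ungapped**: chromosome `A01` and `B01` have identical length and
position-for-position homoeology. This is a deliberate idealisation — real
subgenomes differ by indels and rearrangements — chosen because every
pipeline under study is SNP-only, and because exact co-linearity lets the
bespoke aligner, the pileups and the truth comparison all be exact.

Divergence is spatially heterogeneous. Chromosomes are cut into windows
(default 2 kb) and each window draws a substitution rate from a four-point
mixture — roughly 88% of windows mildly diverged (~3%), 5% at ~22%, 3% at
~38%, and 4% effectively non-homologous (~54%) — rescaled so the *realised*
genome-wide A-vs-B mismatch fraction equals the configured
`homoeolog_divergence` (default 0.07, i.e. ~93% identity). Window
components are allocated in exact stratified counts and shuffled, so the
realised identity is tight around its target. Within a window both branches
mutate independently at the per-branch rate r solving
`d = 2r − (4/3)r²`, which makes the expected pairwise mismatch exactly the
window's d.

Why a mixture rather than a uniform rate: with a uniform 7% rate
essentially every 120 bp probe would hit both subgenomes above the
identity-score-96 cutoff, leaving no single-hit probes and emptying the
lower capture tiers; real subgenome divergence has a median near 93% with
heavy tails. The mixture restores the phenomena the study measures
(single-hit probes, multi-hit rescue, identity-stratified capture) while
keeping the headline identity calibrated. The deepest component is beyond
seed-and-extend sensitivity by design; it stands for regions with no
recoverable homoeologous partner.

## Lines and crosses

The two parents are homozygous at allelic sites (per-bp density
`allelic_snp_density`, default 10⁻³ — denser than a typical cultivated-crop
cross, chosen for statistical power at desk scale) apart from a residual
heterozygous fraction (default 2%). Allelic sites are drawn per subgenome;
a position may be both allelic and homoeologous, and both labels are kept.

RIL pairs are bred explicitly: F1 = one haplotype from each parent; each
selfing generation produces two independent gametes by meiosis with
Poisson(`crossovers_per_chromosome_per_meiosis`, default 1.0) crossovers
per chromosome (disomic inheritance; homoeologous chromosomes never
recombine with each other). After g = `selfing_generations` (default 6)
the shared founder's expected residual heterozygosity is 2^−(g−1); the two
sisters are produced by one extra independent selfing each from that
founder — the minimal model yielding near-isogenic sisters whose differing
blocks are exactly the symmetric difference of their parental-origin
tracks. Crossover rate is nominal, not estimated from any mapping
population.

## Platforms

**Capture (TES).** 100 bp paired reads. Fragment yield at each probe hit
locus is Poisson with mean `depth × p_capture × pitch/(2·read_length)`,
where pitch is the 120 bp probe tiling step — the normalisation that makes
the overlapping footprints of adjacent tiled probes stack to ≈ `depth` per
sample over contiguous targets (isolated spacing probes therefore sit below
nominal depth; capture decays toward target edges). Capture probability is
a two-parameter logistic on probe–target identity, midpoint 0.62 and
steepness 25, calibrated so that ≥75% identity retains ≥90% of maximal
efficiency and a perfect match captures ≥10× more than a 50% match. Only
the threshold behaviour is taken from practice; the curve's shape is a
modelling choice.

**RNA-seq.** 150 bp paired reads drawn uniformly from expressed single-exon
gene models (no splicing), fragment length ~N(320, 40). Mean per-gene
coverage equals the requested depth exactly in expectation, which is what
the Poisson depth check tests.

**GBS.** In-silico ApeKI digest (`G^CWGC`) of each haplotype; fragments
within the size window (default 100–500 bp) emit 64 bp single-end reads
from both ends, Poisson(depth/2) per end per haplotype.

All platforms add uniform per-base substitution errors
(`sequencing_error_rate`, default 10⁻³); quality strings are flat. Reads
carry truth tags (chromosome, fragment coordinates, haplotype) that
re-locate them exactly when the error rate is zero.

**Array.** Markers are sampled from known truth sites; a configurable
fraction (default 15%) comes from homoeologous sites and genotypes as
heterozygous in every sample — the confounded-marker signature described
for real arrays. Genotype miscalls (default 1%) and missingness (2%) are
applied independently per entry.

## Alignment

Exact-seed (k = 21), ungapped extension, mismatch budget 6% of read length,
both strands, fully vectorised. `separate_ab` keeps the best placement per
subgenome ("overall" retention): a read can legitimately appear once on
each reference, which is precisely the homoeologous-stacking behaviour the
M1/M4 pipelines must cope with. `concatenated_ab` keeps only reads whose
best placement is strictly better than any alternative (ties model MAPQ-0
multi-mappers), and pairs must be concordant (one chromosome, opposite
strands, insert 100–600 bp). Probe mapping uses the same engine with k = 10
and 24 spread seeds so that homoeologous loci down to ~60% identity remain
findable; its sensitivity floor (~0.55 per-base identity) is documented
above as a modelled non-homologous class.

## Calling and filtering

Candidates are sites where any sample shows ≥ 2 non-reference reads; the
alternate allele is the pooled majority non-reference base (sites are
treated as biallelic; a third allele at one site is counted toward neither
and effectively ignored). Diagnostic (anchor) sites require, in every
sample, an alternate fraction within [0.2, 0.8] at depth ≥ 4 — a band wide
enough to tolerate 30× binomial sampling. In unique-retention pipelines
cross-subgenome reads are largely absent, so few diagnostics exist and the
anchor filter passes most candidates unfiltered with an explicit
`anchored = False` flag; M3 therefore usually coincides with M2 on this
simulator — a structural property, not a bug.

The haplotype filter assigns read units (pairs for paired platforms —
giving the long-range span — single reads otherwise) to subgenome
partitions by majority vote over the diagnostic alleles they carry; units
reaching no diagnostic form an unanchored partition. A sample's allele at a
candidate is called inside a partition only with ≥ 4 consistent units and
≥ 90% agreement; a record is emitted only when the partitions where both
samples are called show exactly one differing allele pair. Candidates whose
alleles separate the partitions themselves (homoeologous) or that stay
mixed within a sample produce no call, which is why these pipelines emit no
heterozygous class. The machine-learning rescoring step present in the
original tool chain has no desk-scale mechanism and is a declared no-op
pass-through flag.

Because the subgenomes are co-linear, the separate-reference pipelines can
rediscover one allelic SNP at the same coordinate on both references;
records that are exact homoeolog-partner duplicates (same position, same
alleles, same genotypes) are deduplicated keeping the A-subgenome copy.

## Concordance and graphical maps

A sequencing SNP is validated iff an array marker at the same chromosome
and position is polymorphic between the two samples and the unordered
allele-pair genotypes match. Discordant overlapped loci are partitioned
into: het-from-sequence vs hom-on-array, hom-from-sequence vs het-on-array,
allele mismatch, and monomorphic-on-array. Percentages are always
recomputed from integer counts and rounded half-up to two decimals; an
empty overlap reports a null percentage (a dash), never 0.

The combined SNP table unions the homozygous records of the complementary
depth (M2) and haplotype (M4) routes per platform with the array loci,
resolves cross-platform genotype conflicts by majority (ties drop the
locus, logged), and keeps only loci homozygous-polymorphic between the
parents. Sister RILs are genotyped at those loci from their own capture
pileups by the same depth rule, falling back to the array where sequencing
left no call. Qualifying SNPs (both sisters homozygous and different) merge
into regions while consecutive SNPs are within `merge_distance` and the
sister-origin phase is unchanged; a phase flip always splits, so one region
is one origin contrast. No published rule fixes the merge span; it is a
required, logged parameter (desk-scale default 25 kb against 250 kb
chromosomes; a megabase-scale genome would use ~1 Mb).

## Problem sizes and numerical choices

Default study conditions used by the tests and the acceptance script:
2 chromosomes × 250 kb per subgenome (1 Mb total), divergence 0.07, 30×
capture depth, error 10⁻³, six lines, 400 array markers, fixed seeds.
These sizes are the package's own desk-scale choice; they give ~10⁵ reads
per sample and a complete end-to-end run in well under a minute, while
every rate the study turns on (divergence, depth thresholds, capture
cutoffs, error rates) keeps its full-scale value. Determinism is absolute:
all randomness flows from `numpy.random.default_rng` seeded from one
integer, ties in alignment and selection break by lowest coordinate, and
two runs with one seed produce byte-identical manifests.

## What passing tests show — and what they do not

The suite demonstrates that the pipeline mechanics are correct on data
satisfying the generator's assumptions: ungapped co-linear subgenomes,
uniform error, single-exon transcripts, unbiased capture around probe
loci. On such data the filters are near-perfect (diagnostic detection
precision/recall ≥ 0.95 against assayable truth sites; haplotype-pipeline
precision ≥ 0.9). Real data adds indels, repeats, splicing, GC-dependent
capture bias, base-quality structure and reference error; the validation
rates observed there (e.g. ~79–82% array concordance for the haplotype
route) are far below the simulator's, and nothing here certifies those
absolute levels — only the *ordering* of strategies (haplotype > depth-only
> anchor-on-overall for homozygous-SNP quality; depth and haplotype routes
complementary), which the simulation reproduces. Recall of
diagnostic-site detection is reported against *assayable* sites — those
where reads of both true subgenome origins cover the locus at calling depth
with the cross-origin fraction inside [0.25, 0.75] — because a site whose
second allele was never sampled is undetectable in principle.
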