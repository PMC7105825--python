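# tetrasnp

SNP genotyping in an allotetraploid genome, end to end, on synthetic data
with known ground truth.

Allotetraploid crops such as cultivated peanut carry two highly similar
subgenomes (A and B, ~93% identity). Any short read from one subgenome may
align to its homoeologous locus on the other, so a naive variant caller
reports two confounded classes of "SNPs":

- **homoeologous SNPs** — fixed differences between the A and B subgenomes
  inside every individual (false polymorphisms for genetic mapping), and
- **allelic SNPs** — true polymorphisms between individuals at one
  subgenome locus (the markers a breeder wants).

`tetrasnp` re-creates, as a tested pipeline on simulated data, a comparative
study of the strategies used to separate the two classes: capture-probe
panel design, target-enrichment efficiency evaluation, five
alignment/filtering pipelines, SNP-array concordance validation, and
graphical-genotype mapping of the polymorphic regions between near-isogenic
sister recombinant inbred lines (RILs) that differ in a single phenotype
(nodulating vs non-nodulating).

## The five pipelines

| id | reference | reads used | filter |
|----|-----------|------------|--------|
| M1 | A and B separately | all mapped | homoeolog-anchor + read depth |
| M2 | concatenated A+B | uniquely mapped | read depth |
| M3 | concatenated A+B | uniquely mapped | homoeolog-anchor + read depth |
| M4 | A and B separately | all mapped | read(-pair) haplotypes |
| M5 | concatenated A+B | uniquely mapped | read(-pair) haplotypes |

Depth rules: a heterozygous call needs ≥ 2 reads per allele; a homozygous
call needs ≥ 4 reads on the majority allele with the minor allele below 2.
The **anchor filter** partitions the reads covering a candidate SNP by the
allele they carry at nearby homoeolog-diagnostic sites (sites heterozygous
at balanced depth in *every* sample) and keeps the candidate only if its
variation is confined to one subgenome partition. The **haplotype filter**
calls each sample's allele inside one subgenome haplotype background and
emits only homozygous inter-sample differences.

Every input is produced by the package's own generator with full ground
truth: two co-linear subgenomes diverged from one ancestor (heterogeneous
divergence, mean 7%), two homozygous-divergent parents, two F6-derived
sister-RIL pairs bred by simulated selfing with Poisson crossovers, capture
/ RNA-seq / genotyping-by-sequencing (GBS, in-silico ApeKI digest, 64 bp
reads) platforms, and a SNP-array genotype table with configurable error.

## Worked example

The numbered drivers under `analysis/` run the whole study at desk scale
(2 chromosomes × 250 kb per subgenome, 30× capture depth, seed 1) and write
their tables under `results/`:

```bash
python analysis/01_simulate_cohort.py
python analysis/02_design_probes.py
python analysis/04_call_snps.py
```

prints, among other things:

```
subgenomes: 500,000 bp each; A-vs-B identity 92.97% (35,138 homoeologous sites)
allelic sites between parents: 1,036; gene models: 160
...
tiled 2676 probes over 160 gene models
redundancy removal kept 1603 (59.9%)
1603 probes hit the genome; 339 are single-hit at identity score >= 96
selected panel of 749 probes: {'multi_hit_rescue': 578, 'class1_single': 155, ...}
...
tes:
pipeline  total  heterozygous  homozygous
      M1    231           205          26
      M2    217            36         181
      M3    217            36         181
      M4    180             0         180
      M5    181             0         181
```

Reading the output: the subgenome identity lands on the configured ~93%;
the panel keeps every single-hit probe of a targeted gene and rescues
multi-hit probes only for genes with no unique probe. In the pipeline
table, M1 is dominated by heterozygous calls — reads from both subgenomes
stack on one reference, so true homozygous differences look heterozygous —
while the haplotype pipelines (M4, M5) emit homozygous SNPs only, at the
highest validation rates against the simulated array
(`analysis/05_array_concordance.py`), and M2 and M4 recover partly
disjoint SNP sets, so combining them raises recall. The final driver
(`analysis/06_graphical_maps.py`) merges all platforms, genotypes the
sister RILs, and reduces runs of phase-consistent sister differences to the
candidate regions that harbour the phenotype-controlling genes.

The same stages are available as a CLI (`tetrasnp simulate`,
`design-probes`, `capture-metrics`, `call`, `concordance`, `graphmap`,
`run`) and as one orchestrated call, `tetrasnp.workflow.run_all`, which
also emits a manifest of per-stage output hashes — two runs with the same
seed produce byte-identical manifests.

## Layout

```
src/tetrasnp/      library: simcore (generator), probekit, capmetrics,
                   subalign, snpcall, concord, graphmap, evaluate, workflow, cli
analysis/          numbered narrative drivers writing results/
tests/             pytest suite incl. end-to-end acceptance checks
scripts/           acceptance.py
docs/methods.md    model assumptions, parameter choices, limitations
```
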