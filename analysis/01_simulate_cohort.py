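#!/usr/bin/env python
"""Simulate the study cohort: two subgenomes, two parents, two sister-RIL pairs.

Writes the truth genomes, gene models, allelic/homoeologous site catalogs,
RIL origin blocks and the array genotype table under results/cohort/.
"""

import sys
from pathlib import Path

import numpy as np

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import SEED, outdir, workflow_config

from tetrasnp.simcore import (
    simulate_array,
    simulate_ril_pair,
    simulate_tetraploid,
    write_gene_models,
    write_truth_vcf,
)
from tetrasnp.workflow import RIL_PAIRS


def main() -> None:
    cfg = workflow_config()
    out = outdir("cohort")
    truth = simulate_tetraploid(cfg.sim)
    identity = 100 * (1 - len(truth.homoeolog_sites) / truth.genome_a.total_length)
    print(f"subgenomes: {truth.genome_a.total_length:,} bp each; "
          f"A-vs-B identity {identity:.2f}% "
          f"({len(truth.homoeolog_sites):,} homoeologous sites)")
    print(f"allelic sites between parents: {len(truth.allelic_sites):,}; "
          f"gene models: {len(truth.gene_models)}")

    truth.genome_a.to_fasta(out / "subgenome_A.fasta")
    truth.genome_b.to_fasta(out / "subgenome_B.fasta")
    write_gene_models(truth.gene_models, out / "gene_models.tsv")
    write_truth_vcf(truth, out / "truth_parental_snps.vcf")
    truth.homoeolog_sites.to_csv(out / "homoeolog_sites.tsv", sep="\t", index=False)

    rng = np.random.default_rng(cfg.sim.seed + 211)
    pairs = {pid: simulate_ril_pair(truth, cfg.sim, names=names, rng=rng)
             for pid, names in RIL_PAIRS.items()}
    for pid, pair in pairs.items():
        pair.truth_polymorphic_blocks.to_csv(
            out / f"truth_blocks_{pid}.tsv", sep="\t", index=False)
        frac = pair.truth_polymorphic_blocks.eval("end - start").sum() / (
            2 * truth.genome_a.total_length)
        print(f"{pid}: founder residual het {pair.founder_het_fraction:.4f} "
              f"(expect ~{2**-(cfg.sim.selfing_generations - 1):.4f}); "
              f"sisters differ over {100 * frac:.2f}% of the genome "
              f"in {len(pair.truth_polymorphic_blocks)} blocks")

    samples = ["P1", "P2"] + [l for names in RIL_PAIRS.values() for l in names]
    array = simulate_array(truth, samples, cfg.n_array_markers, cfg.array_error_rate,
                           cfg.sim.seed + 17, ril_pairs=pairs,
                           missing_rate=cfg.array_missing_rate)
    array.to_csv(out / "array_genotypes.tsv", sep="\t", index=False)
    print(f"array: {len(array)} markers "
          f"({(array.kind == 'homoeolog').sum()} homoeolog-confounded) "
          f"for {len(samples)} samples -> {out / 'array_genotypes.tsv'}")
    print(f"seed {SEED}; outputs in {out}")


if __name__ == "__main__":
    main()
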