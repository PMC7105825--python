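#!/usr/bin/env python
"""Graphical genotypes: merge platforms, genotype the RILs, call polymorphic
regions and annotate candidate genes.

Combines the homozygous parental SNPs from the sequencing pipelines with the
array, genotypes the sister RILs at the combined loci from their capture
reads, and reduces runs of phase-consistent sister differences to candidate
regions. Writes results/graphmap/.
"""

import sys
from pathlib import Path

import numpy as np
import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, outdir, workflow_config

from tetrasnp import graphmap, subalign
from tetrasnp.simcore import ril_haplotypes, simulate_reads, simulate_ril_pair, simulate_tetraploid
from tetrasnp.workflow import RIL_PAIRS, genotype_lines_from_counts


def main() -> None:
    cfg = workflow_config()
    out = outdir("graphmap")
    truth = simulate_tetraploid(cfg.sim)
    rng = np.random.default_rng(cfg.sim.seed + 211)
    pairs = {pid: simulate_ril_pair(truth, cfg.sim, names=names, rng=rng)
             for pid, names in RIL_PAIRS.items()}
    array = pd.read_csv(RESULTS / "cohort" / "array_genotypes.tsv", sep="\t")

    platform_sets = {}
    for platform in ("tes", "rnaseq", "gbs"):
        homs = []
        for pid in ("M2", "M4"):
            rec = pd.read_csv(RESULTS / "snps" / f"{platform}_{pid}.tsv", sep="\t")
            homs.append(rec[rec.zygosity == "homozygous"])
        rec = pd.concat(homs, ignore_index=True).drop_duplicates(["chrom", "pos"])
        platform_sets[platform] = rec.rename(columns={"gt1": "P1", "gt2": "P2"})[
            ["chrom", "pos", "ref", "alt", "P1", "P2"]]
    samples_all = ["P1", "P2"] + [l for names in RIL_PAIRS.values() for l in names]
    platform_sets["array"] = array.rename(
        columns={"allele_ref": "ref", "allele_alt": "alt"})[
        ["chrom", "pos", "ref", "alt", *samples_all]]
    combined = graphmap.merge_platforms(platform_sets, samples=("P1", "P2"))
    print(f"combined non-redundant homozygous parental SNPs: {len(combined)}")

    # genotype the RILs at the combined loci from their capture reads
    panel = pd.read_csv(RESULTS / "probes" / "panel.tsv", sep="\t")
    panel_hits = pd.read_csv(RESULTS / "probes" / "panel_hits.tsv", sep="\t")
    ril_lines = {}
    for pid, pair in pairs.items():
        for line in pair.lines:
            ril_lines[line] = ril_haplotypes(truth, pair, line)
    readsets = simulate_reads(truth, ril_lines, "tes", probes=(panel, panel_hits),
                              depth=cfg.depth_tes,
                              rng=np.random.default_rng(cfg.sim.seed + 404))
    genome_ab = truth.genome_ab
    genomes = (truth.genome_a, truth.genome_b)
    counts = {}
    for line, rs in readsets.items():
        aln = subalign.align_reads(rs, genomes, "concatenated_ab")
        counts[line] = subalign.pileup(aln, rs, genome_ab)
    combined = genotype_lines_from_counts(combined, counts, genome_ab)
    arr_idx = array.set_index(["chrom", "pos"])
    for line in ril_lines:
        missing = combined[line] == "./."
        keys = list(zip(combined.chrom[missing], combined.pos[missing]))
        combined.loc[missing, line] = [
            arr_idx[line].get(k, "./.") if k in arr_idx.index else "./." for k in keys]
    combined.to_csv(out / "combined_snps.tsv", sep="\t", index=False)

    deg = set(truth.gene_models.gene_id[truth.gene_models.is_deg])
    nod = set(truth.gene_models.gene_id[truth.gene_models.is_nod])
    for pid, pair in pairs.items():
        qual = graphmap.filter_ril_polymorphic(combined, pair.lines)
        regions = graphmap.call_regions(qual, cfg.merge_distance, ril_pair=pid)
        annotated = graphmap.annotate_regions(regions, truth.gene_models, deg, nod)
        graphmap.write_regions_bed(regions, out / f"regions_{pid}.bed")
        annotated.to_csv(out / f"regions_{pid}_annotated.tsv", sep="\t", index=False)
        matrix = graphmap.genotype_matrix(qual, pair.lines)
        matrix.to_csv(out / f"graphical_genotypes_{pid}.tsv", sep="\t", index=False)
        print(f"{pid}: {len(qual)} qualifying SNPs -> {len(regions)} polymorphic "
              f"regions (merge distance {cfg.merge_distance:,} bp); "
              f"{int(annotated.n_deg.sum())} DEG and {int(annotated.n_nod.sum())} "
              f"nodulation-ortholog annotations")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
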