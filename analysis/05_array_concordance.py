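#!/usr/bin/env python
"""Validate each pipeline's SNPs against the array; compare pipelines.

Computes per-pipeline overlap and concordance (with discordance classes),
sister-pair monomorphic fractions, and the M2-vs-M4/M5 overlap that shows
the depth and haplotype routes find complementary SNP sets. Writes
results/concordance/.
"""

import sys
from pathlib import Path

import pandas as pd

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import RESULTS, outdir, workflow_config

from tetrasnp import concord


def main() -> None:
    cfg = workflow_config()
    out = outdir("concordance")
    array = pd.read_csv(RESULTS / "cohort" / "array_genotypes.tsv", sep="\t")

    for platform in ("tes", "rnaseq", "gbs"):
        reports = []
        for pid in cfg.pipelines:
            rec = pd.read_csv(RESULTS / "snps" / f"{platform}_{pid}.tsv", sep="\t")
            report, per_locus = concord.overlap_and_score(rec, array, ("P1", "P2"), pid)
            reports.append(report)
            per_locus.to_csv(out / f"{platform}_{pid}_loci.tsv", sep="\t", index=False)
        table = concord.reports_to_table(reports)
        table.to_csv(out / f"{platform}_concordance.tsv", sep="\t", index=False)
        print(f"\n{platform} (n_overlapped / concordance%):")
        print(table[["pipeline", "n_total", "n_overlapped", "n_concordant",
                     "concordance_pct", "het_seq_hom_array", "monomorphic_on_array"]]
              .to_string(index=False))

    for pair in (("E4", "E5"), ("E6", "E7")):
        pct, num, den = concord.monomorphic_fraction(array, pair)
        print(f"\n{pair[0]} & {pair[1]}: {num} of {den} homozygous parental loci "
              f"monomorphic ({pct}%)")

    m2 = pd.read_csv(RESULTS / "snps" / "tes_M2.tsv", sep="\t")
    m4 = pd.read_csv(RESULTS / "snps" / "tes_M4.tsv", sep="\t")
    ov = concord.pipeline_overlap(m2[m2.zygosity == "homozygous"], m4)
    print(f"\nM2-hom vs M4 overlap: shared {ov['shared']}, "
          f"M2-only {ov['only_a']}, M4-only {ov['only_b']} "
          f"({ov['pct_a_covered_by_b']}% of M2 covered) — the two routes are "
          f"complementary")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
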