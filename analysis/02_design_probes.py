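#!/usr/bin/env python
"""Design the capture probe panel: tile, deduplicate, map, select.

Reproduces the panel-construction logic: 120 bp non-overlapping tiles over
gene templates (gene body + 2 kb/1 kb flanks for the nodulation-related
class, CDS only otherwise), redundancy removal, uniqueness scoring at the
identity-score >= 96 cutoff (80% of a 120 bp probe), and three-stage panel
selection. Writes results/probes/.
"""

import sys
from pathlib import Path

sys.path.insert(0, str(Path(__file__).resolve().parent))
from _config import outdir, workflow_config

from tetrasnp import probekit
from tetrasnp.simcore import simulate_tetraploid


def main() -> None:
    cfg = workflow_config()
    out = outdir("probes")
    truth = simulate_tetraploid(cfg.sim)
    genome = truth.genome_ab

    tiled = probekit.tile_probes(truth.gene_models, genome)
    print(f"tiled {len(tiled)} probes over {truth.gene_models.gene_id.nunique()} gene models")
    probes = probekit.deduplicate_probes(tiled)
    print(f"redundancy removal kept {len(probes)} "
          f"({100 * len(probes) / len(tiled):.1f}%)")

    all_hits = probekit.map_probes(probes, genome, hit_cutoff=60)
    hits96 = all_hits[all_hits.identity_score >= cfg.hit_cutoff].copy()
    hits96["n_hits"] = hits96.groupby("probe_id").probe_id.transform("size")
    n_single = int((hits96.groupby("probe_id").size() == 1).sum())
    print(f"{all_hits.probe_id.nunique()} probes hit the genome; "
          f"{n_single} are single-hit at identity score >= {cfg.hit_cutoff}")

    panel = probekit.select_panel(probes, hits96, truth.gene_models, genome,
                                  cfg.fragment_size)
    print(f"selected panel of {len(panel.probes)} probes: {panel.counts}")
    probekit.write_panel(panel, out / "panel.fasta", out / "panel.tsv")
    panel_hits = all_hits[all_hits.probe_id.isin(set(panel.probes.probe_id))]
    panel_hits.to_csv(out / "panel_hits.tsv", sep="\t", index=False)
    probekit.write_hits_bed(panel_hits, out / "panel_hits.bed")
    print(f"outputs in {out}")


if __name__ == "__main__":
    main()
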