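"""End-to-end orchestration: simulate -> design -> sequence -> call -> validate
-> map, with a reproducibility manifest.

The default workflow breeds the six-line cohort (parents P1/P2 and two sister
RIL pairs E4/E5, E6/E7), designs a probe panel, simulates the three
sequencing platforms plus the SNP array, runs the five calling pipelines on
each platform for the parental contrast, validates against the array, and
builds graphical-genotype regions for both RIL pairs.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import capmetrics, concord, graphmap, probekit, snpcall, subalign
from ._kmer import KmerIndex
from ._seq import Genome, encode
from .simcore import (
    RILPair,
    SimConfig,
    TetraploidTruth,
    line_haplotypes,
    ril_haplotypes,
    simulate_array,
    simulate_reads,
    simulate_ril_pair,
    simulate_tetraploid,
)

__version__ = "0.1.0"

PARENTS = ("P1", "P2")
RIL_PAIRS = {"E4E5": ("E4", "E5"), "E6E7": ("E6", "E7")}


@dataclass
class WorkflowConfig:
    """Run-level knobs around the simulation conditions."""

    sim: SimConfig = field(default_factory=SimConfig)
    depth_tes: float = 30.0
    depth_rnaseq: float = 30.0
    depth_gbs: float = 8.0
    n_array_markers: int = 400
    array_error_rate: float = 0.01
    array_missing_rate: float = 0.02
    merge_distance: int = 25_000  # desk-scale region merge span
    hit_cutoff: int = probekit.HIT_CUTOFF
    fragment_size: int = probekit.FRAGMENT_SIZE
    platforms: tuple[str, ...] = ("tes", "rnaseq", "gbs")
    pipelines: tuple[str, ...] = ("M1", "M2", "M3", "M4", "M5")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "WorkflowConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        sim = SimConfig(**raw.pop("sim", {}))
        return cls(sim=sim, **raw)

    def to_dict(self) -> dict:
        out = asdict(self)
        return out


@dataclass
class RunManifest:
    """Config snapshot, seeds and per-stage output hashes; identical manifests
    certify identical runs."""

    version: str
    seed: int
    config: dict
    hashes: dict[str, str]

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(
            {"version": self.version, "seed": self.seed, "config": self.config, "hashes": self.hashes},
            indent=2,
            sort_keys=True,
            default=str,
        )
        if path is not None:
            Path(path).write_text(text)
        return text


def _hash_frame(frame: pd.DataFrame) -> str:
    return hashlib.sha256(frame.to_csv(index=False).encode()).hexdigest()


@dataclass
class RunResult:
    """Everything a downstream consumer or test needs from one run."""

    config: WorkflowConfig
    truth: TetraploidTruth
    pairs: dict[str, RILPair]
    panel: probekit.PanelSelection
    panel_hits: pd.DataFrame
    readsets: dict[str, dict[str, object]]  # platform -> sample -> ReadSet
    alignments: dict[str, dict[str, dict[str, pd.DataFrame]]]  # platform -> mode -> sample
    records: dict[str, dict[str, pd.DataFrame]]  # platform -> pipeline -> records
    capture_ladder: dict[str, pd.DataFrame]  # retention -> per-cutoff summary
    array_table: pd.DataFrame
    reports: dict[str, dict[str, concord.OverlapReport]]  # platform -> pipeline
    combined: pd.DataFrame
    qualifying: dict[str, pd.DataFrame]
    regions: dict[str, list[graphmap.PolymorphicRegion]]
    annotated: dict[str, pd.DataFrame]
    mapping_stats: pd.DataFrame
    manifest: RunManifest


def _stack_separate(aln_by_sample: dict[str, pd.DataFrame]) -> pd.DataFrame:
    return pd.concat(list(aln_by_sample.values()), ignore_index=True)


def genotype_lines_from_counts(
    table: pd.DataFrame,
    counts_by_line: dict[str, np.ndarray],
    genome_ab: Genome,
    hom_min: int = snpcall.HOM_MIN,
    het_min: int = snpcall.HET_MIN,
) -> pd.DataFrame:
    """Depth-rule genotypes for extra lines at the table's loci.

    Loci without a confident call get './.'.
    """
    out = table.copy()
    gpos = np.array(
        [genome_ab.offset(c) for c in table.chrom], dtype=np.int64
    ) + table.pos.to_numpy(dtype=np.int64)
    ref_codes = np.array([encode(b)[0] for b in table.ref], dtype=np.uint8)
    alt_codes = np.array([encode(b)[0] for b in table.alt], dtype=np.uint8)
    for line, counts in counts_by_line.items():
        ref_n = counts[ref_codes, gpos]
        alt_n = counts[alt_codes, gpos]
        codes = snpcall._call_genotypes_vec(ref_n, alt_n, hom_min, het_min)
        strings = np.where(
            codes == 0,
            [f"{b}/{b}" for b in table.ref],
            np.where(
                codes == 2,
                [f"{b}/{b}" for b in table.alt],
                np.where(
                    codes == 1,
                    ["/".join(sorted((r, a))) for r, a in zip(table.ref, table.alt)],
                    "./.",
                ),
            ),
        )
        out[line] = strings
    return out


def run_all(config: WorkflowConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute every stage on the synthetic six-line cohort.

    Any stage failure raises with a stage-tagged message. With ``out_dir``
    the report bundle (panel, hits, VCFs, tables, regions, manifest) is
    written there.
    """
    hashes: dict[str, str] = {}
    stage = "simulate"
    try:
        truth = simulate_tetraploid(config.sim)
        rng = np.random.default_rng(config.sim.seed + 211)
        pairs = {
            pid: simulate_ril_pair(truth, config.sim, names=names, rng=rng)
            for pid, names in RIL_PAIRS.items()
        }
        hashes["truth_allelic"] = _hash_frame(truth.allelic_sites)
        hashes["truth_homoeolog"] = _hash_frame(truth.homoeolog_sites)

        stage = "probe-design"
        probes = probekit.tile_probes(truth.gene_models, truth.genome_ab)
        probes = probekit.deduplicate_probes(probes)
        all_hits = probekit.map_probes(probes, truth.genome_ab, hit_cutoff=60)
        hits96 = all_hits[all_hits.identity_score >= config.hit_cutoff].copy()
        hits96["n_hits"] = hits96.groupby("probe_id").probe_id.transform("size")
        panel = probekit.select_panel(
            probes, hits96, truth.gene_models, truth.genome_ab, config.fragment_size
        )
        panel_ids = set(panel.probes.probe_id)
        panel_hits = all_hits[all_hits.probe_id.isin(panel_ids)].reset_index(drop=True)
        hashes["panel"] = _hash_frame(panel.probes.drop(columns=["sequence"]))

        stage = "sequencing"
        lines_all = {p: line_haplotypes(truth, p) for p in PARENTS}
        for pid, names in RIL_PAIRS.items():
            for line in names:
                lines_all[line] = ril_haplotypes(truth, pairs[pid], line)
        readsets: dict[str, dict[str, object]] = {}
        if "tes" in config.platforms:
            readsets["tes"] = simulate_reads(
                truth,
                lines_all,
                "tes",
                probes=(panel.probes, panel_hits),
                depth=config.depth_tes,
                rng=np.random.default_rng(config.sim.seed + 401),
            )
        parents_only = {p: lines_all[p] for p in PARENTS}
        if "rnaseq" in config.platforms:
            readsets["rnaseq"] = simulate_reads(
                truth,
                parents_only,
                "rnaseq",
                depth=config.depth_rnaseq,
                rng=np.random.default_rng(config.sim.seed + 402),
            )
        if "gbs" in config.platforms:
            readsets["gbs"] = simulate_reads(
                truth,
                parents_only,
                "gbs",
                depth=config.depth_gbs,
                rng=np.random.default_rng(config.sim.seed + 403),
            )

        stage = "alignment"
        genomes = (truth.genome_a, truth.genome_b)
        genome_ab = truth.genome_ab
        indexes = {
            "A": KmerIndex.build(truth.genome_a, subalign.READ_SEED_K),
            "B": KmerIndex.build(truth.genome_b, subalign.READ_SEED_K),
            "AB": KmerIndex.build(genome_ab, subalign.READ_SEED_K),
        }
        alignments: dict[str, dict[str, dict[str, pd.DataFrame]]] = {}
        stats_rows = []
        for platform, sets in readsets.items():
            alignments[platform] = {"separate_ab": {}, "concatenated_ab": {}}
            for sample, rs in sets.items():
                if platform != "tes" and sample not in PARENTS:
                    continue
                sep = subalign.align_reads(rs, genomes, "separate_ab", indexes=indexes)
                cat = subalign.align_reads(rs, genomes, "concatenated_ab", indexes=indexes)
                alignments[platform]["separate_ab"][sample] = sep
                alignments[platform]["concatenated_ab"][sample] = cat
                n_mates = rs.n_reads
                overall = sep.drop_duplicates(["read_id", "mate"]) if len(sep) else sep
                stats_rows.append(
                    {
                        "platform": platform,
                        "sample": sample,
                        "n_reads": n_mates,
                        "overall_rate": len(overall) / n_mates if n_mates else 0.0,
                        "unique_rate": len(cat) / n_mates if n_mates else 0.0,
                    }
                )
        mapping_stats = pd.DataFrame(stats_rows)
        hashes["mapping_stats"] = _hash_frame(mapping_stats.round(6))

        stage = "capture-metrics"
        capture_ladder = {}
        if "tes" in readsets:
            overall_aln = _stack_separate(
                {s: alignments["tes"]["separate_ab"][s] for s in PARENTS}
            )
            unique_aln = pd.concat(
                [alignments["tes"]["concatenated_ab"][s] for s in PARENTS],
                ignore_index=True,
            )
            capture_ladder["overall"] = capmetrics.cutoff_ladder_summaries(
                panel_hits, overall_aln, genome_ab
            )
            capture_ladder["unique"] = capmetrics.cutoff_ladder_summaries(
                panel_hits, unique_aln, genome_ab
            )
            hashes["capture_ladder"] = _hash_frame(
                pd.concat(capture_ladder.values(), ignore_index=True).round(6)
            )

        stage = "snp-calling"
        records: dict[str, dict[str, pd.DataFrame]] = {}
        for platform, sets in readsets.items():
            records[platform] = {}
            parent_sets = {p: sets[p] for p in PARENTS}
            for pid in config.pipelines:
                cfg = snpcall.PipelineConfig.from_id(pid)
                aln = {
                    p: alignments[platform][cfg.reference_mode][p] for p in PARENTS
                }
                records[platform][pid] = snpcall.run_pipeline(
                    cfg, parent_sets, genomes, samples=PARENTS, alignments=aln
                )
            hashes[f"records_{platform}"] = _hash_frame(
                pd.concat(records[platform].values(), ignore_index=True)
            )

        stage = "array"
        samples_all = list(PARENTS) + [l for names in RIL_PAIRS.values() for l in names]
        array_table = simulate_array(
            truth,
            samples_all,
            config.n_array_markers,
            config.array_error_rate,
            config.sim.seed + 17,
            ril_pairs=pairs,
            missing_rate=config.array_missing_rate,
        )
        hashes["array"] = _hash_frame(array_table)

        stage = "concordance"
        reports: dict[str, dict[str, concord.OverlapReport]] = {}
        for platform in records:
            reports[platform] = {}
            for pid, rec in records[platform].items():
                report, _ = concord.overlap_and_score(rec, array_table, PARENTS, pid)
                reports[platform][pid] = report

        stage = "graphical-map"
        platform_sets = {}
        for platform in records:
            chosen = []
            for pid in ("M2", "M4"):
                if pid in records[platform]:
                    rec = records[platform][pid]
                    chosen.append(rec[rec.zygosity == "homozygous"])
            if chosen:
                rec = pd.concat(chosen, ignore_index=True).drop_duplicates(["chrom", "pos"])
                platform_sets[platform] = rec.rename(columns={"gt1": "P1", "gt2": "P2"})[
                    ["chrom", "pos", "ref", "alt", "P1", "P2"]
                ]
        arr_set = array_table.rename(
            columns={"allele_ref": "ref", "allele_alt": "alt"}
        )[["chrom", "pos", "ref", "alt", *samples_all]]
        platform_sets["array"] = arr_set
        combined = graphmap.merge_platforms(platform_sets, samples=PARENTS)

        # genotype the RIL lines at the combined loci from their capture reads
        ril_lines = [l for names in RIL_PAIRS.values() for l in names]
        counts_by_line = {}
        if "tes" in readsets:
            for line in ril_lines:
                aln = alignments["tes"]["concatenated_ab"][line]
                counts_by_line[line] = subalign.pileup(
                    aln, readsets["tes"][line], genome_ab
                )
        combined = genotype_lines_from_counts(combined, counts_by_line, genome_ab)
        # fall back to array genotypes where sequencing left a locus uncalled
        arr_idx = array_table.set_index(["chrom", "pos"])
        for line in ril_lines:
            missing = combined[line] == "./."
            if missing.any():
                keys = list(zip(combined.chrom[missing], combined.pos[missing]))
                fill = [
                    arr_idx[line].get(key, "./.") if key in arr_idx.index else "./."
                    for key in keys
                ]
                combined.loc[missing, line] = fill
        hashes["combined"] = _hash_frame(combined)

        qualifying = {}
        regions = {}
        annotated = {}
        deg = set(truth.gene_models.gene_id[truth.gene_models.is_deg])
        nod = set(truth.gene_models.gene_id[truth.gene_models.is_nod])
        for pid, names in RIL_PAIRS.items():
            qual = graphmap.filter_ril_polymorphic(combined, names, PARENTS)
            qualifying[pid] = qual
            regs = graphmap.call_regions(qual, config.merge_distance, ril_pair=pid)
            regions[pid] = regs
            annotated[pid] = graphmap.annotate_regions(regs, truth.gene_models, deg, nod)
            hashes[f"regions_{pid}"] = _hash_frame(graphmap.regions_to_frame(regs))

        manifest = RunManifest(
            version=__version__,
            seed=config.sim.seed,
            config=config.to_dict(),
            hashes=hashes,
        )
    except Exception as err:  # pragma: no cover - stage tagging
        raise RuntimeError(f"stage '{stage}' failed: {err}") from err

    result = RunResult(
        config=config,
        truth=truth,
        pairs=pairs,
        panel=panel,
        panel_hits=panel_hits,
        readsets=readsets,
        alignments=alignments,
        records=records,
        capture_ladder=capture_ladder,
        array_table=array_table,
        reports=reports,
        combined=combined,
        qualifying=qualifying,
        regions=regions,
        annotated=annotated,
        mapping_stats=mapping_stats,
        manifest=manifest,
    )
    if out_dir is not None:
        write_bundle(result, Path(out_dir))
    return result


def write_bundle(result: RunResult, out_dir: Path) -> None:
    """Write the report bundle: panel, hits, summaries, VCFs, regions, manifest."""
    out_dir.mkdir(parents=True, exist_ok=True)
    probekit.write_panel(result.panel, out_dir / "panel.fasta", out_dir / "panel.tsv")
    probekit.write_hits_bed(result.panel_hits, out_dir / "panel_hits.bed")
    result.mapping_stats.to_csv(out_dir / "mapping_stats.tsv", sep="\t", index=False)
    for retention, ladder in result.capture_ladder.items():
        ladder.to_csv(out_dir / f"capture_{retention}.tsv", sep="\t", index=False)
    result.array_table.to_csv(out_dir / "array_genotypes.tsv", sep="\t", index=False)
    genomes = (result.truth.genome_a, result.truth.genome_b)
    for platform, per_pipeline in result.records.items():
        for pid, rec in per_pipeline.items():
            snpcall.write_vcf(rec, genomes, out_dir / f"{platform}_{pid}.vcf")
        snpcall.zygosity_summary(per_pipeline).to_csv(
            out_dir / f"{platform}_zygosity.tsv", sep="\t", index=False
        )
        concord.reports_to_table(list(result.reports[platform].values())).to_csv(
            out_dir / f"{platform}_concordance.tsv", sep="\t", index=False
        )
    result.combined.to_csv(out_dir / "combined_snps.tsv", sep="\t", index=False)
    for pid, regs in result.regions.items():
        graphmap.write_regions_bed(regs, out_dir / f"regions_{pid}.bed")
        result.annotated[pid].to_csv(
            out_dir / f"regions_{pid}_annotated.tsv", sep="\t", index=False
        )
    result.manifest.to_json(out_dir / "manifest.json")
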