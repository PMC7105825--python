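"""Capture-probe design, uniqueness evaluation and panel selection.

Probes are 120 bp non-overlapping tiles over class-appropriate templates
(gene body plus 2 kb upstream / 1 kb downstream flanks for class1 genes,
coding sequence only for class2 and resistance genes). Uniqueness is scored
by ungapped placement against the combined subgenomes using the alignment
identity metric ``identity_score = alignment_length x percent_identity``
(on a 120 bp probe, 96 corresponds to an 80% match). Panel selection keeps
all single-hit probes of targeted genes, rescues genes with only multi-hit
probes (2-4 hits), and spreads the remainder one probe per fixed-size genome
fragment.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import _kmer
from ._seq import Genome, decode, encode

PROBE_LENGTH = 120
HIT_CUTOFF = 96
FRAGMENT_SIZE = 44_300

#: seed size for probe mapping; small enough to recover ~60-80% diverged
#: homoeologous loci down to the 50%-identity reporting floor
PROBE_SEED_K = 10
PROBE_SEEDS = 24


@dataclass(frozen=True)
class Probe:
    """One fixed-length capture probe tiled from a gene template."""

    id: str
    source_gene_id: str
    source_class: str
    sequence: str
    chrom: str
    design_coordinate: int  # template-forward start on the source chromosome

    def __post_init__(self) -> None:
        if len(self.sequence) != PROBE_LENGTH:
            raise ValueError(f"probe {self.id} is not {PROBE_LENGTH} bp")


def probes_to_frame(probes: list[Probe]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "probe_id": p.id,
                "gene_id": p.source_gene_id,
                "cls": p.source_class,
                "chrom": p.chrom,
                "design_coordinate": p.design_coordinate,
                "sequence": p.sequence,
            }
            for p in probes
        ],
        columns=["probe_id", "gene_id", "cls", "chrom", "design_coordinate", "sequence"],
    )


def tile_probes(
    gene_models: pd.DataFrame,
    genome: Genome,
    flank_up: int = 2_000,
    flank_down: int = 1_000,
    probe_length: int = PROBE_LENGTH,
    max_genes_per_orthogroup: int = 4,
) -> list[Probe]:
    """Tile non-overlapping probes over each gene's design template.

    class1 templates span the gene with its upstream/downstream flanks
    (clipped at chromosome ends); class2 and resistance templates are the
    coding interval only. Within a class1 orthogroup only the top
    ``max_genes_per_orthogroup`` genes by similarity score are used. The
    trailing remainder shorter than one probe is dropped; templates shorter
    than one probe yield no probes.
    """
    genes = gene_models.copy()
    drop: set[str] = set()
    if "orthogroup" in genes.columns:
        c1 = genes[(genes.cls == "class1") & (genes.orthogroup != "")]
        for _, grp in c1.groupby("orthogroup", sort=True):
            if len(grp) > max_genes_per_orthogroup:
                ranked = grp.sort_values(
                    ["similarity", "gene_id"], ascending=[False, True]
                )
                drop.update(ranked.gene_id.iloc[max_genes_per_orthogroup:])
    probes: list[Probe] = []
    for gene in genes.itertuples(index=False):
        if gene.gene_id in drop:
            continue
        chrom_len = genome.length(gene.chrom)
        if gene.cls == "class1":
            t_start = max(gene.start - flank_up, 0)
            t_end = min(gene.end + flank_down, chrom_len)
        else:
            t_start, t_end = gene.start, gene.end
        template = genome.chroms[gene.chrom][t_start:t_end]
        n_tiles = len(template) // probe_length
        for i in range(n_tiles):
            off = i * probe_length
            probes.append(
                Probe(
                    id=f"{gene.gene_id}_p{i:03d}",
                    source_gene_id=gene.gene_id,
                    source_class=gene.cls,
                    sequence=decode(template[off : off + probe_length]),
                    chrom=gene.chrom,
                    design_coordinate=t_start + off,
                )
            )
    return probes


def map_probes(
    probes: list[Probe] | pd.DataFrame,
    genome: Genome,
    hit_cutoff: int = HIT_CUTOFF,
) -> pd.DataFrame:
    """Place probes on both strands of the genome by seed-and-extend.

    A hit is any ungapped locus with
    ``identity_score = alignment_length x percent_identity >= hit_cutoff``
    (alignment length is the full probe length in the ungapped model).
    Returns one row per hit: probe_id, chrom, start, end, strand,
    percent_identity, alignment_length, identity_score, and the per-probe
    hit count ``n_hits``.
    """
    frame = probes if isinstance(probes, pd.DataFrame) else probes_to_frame(probes)
    if len(frame) == 0:
        return pd.DataFrame(
            columns=[
                "probe_id",
                "chrom",
                "start",
                "end",
                "strand",
                "percent_identity",
                "alignment_length",
                "identity_score",
                "n_hits",
            ]
        )
    queries = np.stack([encode(s) for s in frame.sequence])
    length = queries.shape[1]
    max_mm = length - int(np.ceil(hit_cutoff))
    index = _kmer.KmerIndex.build(genome, PROBE_SEED_K)
    hits = _kmer.search(queries, index, max_mm, n_seeds=PROBE_SEEDS)
    cidx, local = genome.locate(hits.start)
    identity = (length - hits.mismatches) / length
    out = pd.DataFrame(
        {
            "probe_id": frame.probe_id.to_numpy()[hits.qidx],
            "chrom": np.asarray(genome.names, dtype=object)[cidx],
            "start": local,
            "end": local + length,
            "strand": np.where(hits.strand == 0, "+", "-"),
            "percent_identity": identity,
            "alignment_length": length,
            "identity_score": length * identity,
        }
    )
    out = out[out.identity_score >= hit_cutoff].reset_index(drop=True)
    out["n_hits"] = out.groupby("probe_id").probe_id.transform("size")
    return out


def deduplicate_probes(
    probes: list[Probe],
    identity: float = 0.8,
    coverage: float = 0.8,
) -> list[Probe]:
    """Greedy redundancy removal in the style of CD-HIT-EST.

    Probes are processed in a deterministic order (length descending, then
    sequence lexicographic); each joins the first cluster whose representative
    matches at >= ``identity`` over >= ``coverage`` of both sequences on
    either strand, else founds a new cluster. Since probes share one fixed
    length, coverage is always complete and the test reduces to whole-length
    identity on the forward or reverse-complement strand. Representatives are
    returned in input order.
    """
    del coverage  # complete by construction for fixed-length probes
    if not probes:
        return []
    order = sorted(
        range(len(probes)), key=lambda i: (-len(probes[i].sequence), probes[i].sequence)
    )
    length = len(probes[order[0]].sequence)
    min_matches = identity * length
    reps: list[int] = []
    # preallocated representative matrices (forward and reverse complement)
    rep_fwd = np.empty((len(probes), length), dtype=np.uint8)
    rep_rc = np.empty((len(probes), length), dtype=np.uint8)
    n_reps = 0
    for i in order:
        seq = encode(probes[i].sequence)
        if n_reps:
            matches_f = (rep_fwd[:n_reps] == seq).sum(axis=1)
            matches_r = (rep_rc[:n_reps] == seq).sum(axis=1)
            if (matches_f >= min_matches).any() or (matches_r >= min_matches).any():
                continue
        reps.append(i)
        rep_fwd[n_reps] = seq
        rep_rc[n_reps] = (3 - seq)[::-1]
        n_reps += 1
    return [probes[i] for i in sorted(reps)]


@dataclass
class PanelSelection:
    """Selected panel with the reason each probe was kept."""

    probes: pd.DataFrame  # probe table + selection_reason column
    fragment_size: int
    counts: dict[str, int]

    @property
    def probe_ids(self) -> list[str]:
        return list(self.probes.probe_id)


def select_panel(
    probes: list[Probe] | pd.DataFrame,
    hits: pd.DataFrame,
    gene_models: pd.DataFrame,
    genome: Genome,
    fragment_size: int = FRAGMENT_SIZE,
    target_panel_size: int | None = None,
) -> PanelSelection:
    """Three-stage panel selection.

    1. every single-hit probe of a class1 or resistance gene;
    2. probes with 2-4 hits, rescued only for class1/resistance genes that
       have no single-hit probe;
    3. the genome partitioned into consecutive ``fragment_size`` windows;
       each window not already intersected by a selected probe's hits
       receives the lowest-coordinate single-hit class2 probe located in it.

    If ``target_panel_size`` is given, excess spacing probes are trimmed
    deterministically from the highest coordinates.
    """
    frame = probes if isinstance(probes, pd.DataFrame) else probes_to_frame(probes)
    n_hits = hits.groupby("probe_id").size() if len(hits) else pd.Series(dtype=int)
    frame = frame.assign(n_hits=frame.probe_id.map(n_hits).fillna(0).astype(int))
    single = frame[frame.n_hits == 1]
    targeted = {"class1", "resistance"}

    stage1 = single[single.cls.isin(targeted)]
    selected_ids = dict.fromkeys(stage1.probe_id)
    reasons = {
        pid: ("class1_single" if cls == "class1" else "resistance_single")
        for pid, cls in zip(stage1.probe_id, stage1.cls)
    }

    covered_genes = set(stage1.gene_id)
    multi = frame[(frame.n_hits >= 2) & (frame.n_hits <= 4) & frame.cls.isin(targeted)]
    rescue = multi[~multi.gene_id.isin(covered_genes)]
    for pid in rescue.probe_id:
        selected_ids.setdefault(pid)
        reasons.setdefault(pid, "multi_hit_rescue")

    # stage 3: one single-hit class2 probe per uncovered genome fragment
    frag_index: dict[tuple[str, int], bool] = {}
    sel_hits = hits[hits.probe_id.isin(selected_ids)] if len(hits) else hits
    covered_frags = set()
    if len(sel_hits):
        for row in sel_hits.itertuples(index=False):
            for frag in range(row.start // fragment_size, (row.end - 1) // fragment_size + 1):
                covered_frags.add((row.chrom, frag))
    del frag_index

    spacing_rows = []
    c2_single = single[single.cls == "class2"]
    if len(c2_single):
        c2_hits = hits[hits.probe_id.isin(set(c2_single.probe_id))]
        c2_hits = c2_hits.sort_values(["chrom", "start", "probe_id"], kind="stable")
        taken: set[tuple[str, int]] = set()
        for row in c2_hits.itertuples(index=False):
            frag = (row.chrom, row.start // fragment_size)
            if frag in covered_frags or frag in taken:
                continue
            taken.add(frag)
            spacing_rows.append(row.probe_id)
    for pid in spacing_rows:
        selected_ids.setdefault(pid)
        reasons.setdefault(pid, "spacing")

    panel = frame[frame.probe_id.isin(selected_ids)].copy()
    panel["selection_reason"] = panel.probe_id.map(reasons)
    if target_panel_size is not None and len(panel) > target_panel_size:
        excess = len(panel) - target_panel_size
        spacing = panel[panel.selection_reason == "spacing"].sort_values(
            ["chrom", "design_coordinate"], kind="stable"
        )
        drop_ids = set(spacing.probe_id.iloc[len(spacing) - excess :])
        panel = panel[~panel.probe_id.isin(drop_ids)]
    panel = panel.sort_values(["chrom", "design_coordinate", "probe_id"], kind="stable")
    panel = panel.reset_index(drop=True)
    counts = panel.selection_reason.value_counts().to_dict()
    return PanelSelection(probes=panel, fragment_size=fragment_size, counts=counts)


def write_panel(panel: PanelSelection, fasta_path, tsv_path) -> None:
    """Panel as FASTA plus a probe metadata TSV."""
    with open(fasta_path, "w") as fh:
        for row in panel.probes.itertuples(index=False):
            fh.write(f">{row.probe_id}\n{row.sequence}\n")
    panel.probes.drop(columns=["sequence"]).to_csv(tsv_path, sep="\t", index=False)


def write_hits_bed(hits: pd.DataFrame, path) -> None:
    """Hits as BED6-compatible TSV with identity_score in the score column."""
    bed = pd.DataFrame(
        {
            "chrom": hits.chrom,
            "start": hits.start,
            "end": hits.end,
            "name": hits.probe_id,
            "score": hits.identity_score.round(2),
            "strand": hits.strand,
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)
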