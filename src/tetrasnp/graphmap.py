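"""Graphical genotypes: merge platforms, filter RIL-polymorphic SNPs, call
polymorphic regions, and annotate candidate genes.

The qualifying markers are homozygous SNPs polymorphic both between the
original parents and between the two near-isogenic sister lines; runs of
consecutive qualifying SNPs with consistent sister-origin phase merge into
polymorphic regions — the intervals where the sisters carry different
parental alleles and where genes controlling the contrasting phenotype must
reside.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from intervaltree import IntervalTree

logger = logging.getLogger(__name__)

DEFAULT_MERGE_DISTANCE = 1_000_000


def _is_hom(gt: str) -> bool:
    a, b = gt.split("/")
    return a == b


def merge_platforms(
    snp_sets: dict[str, pd.DataFrame],
    samples: tuple[str, ...] = ("P1", "P2"),
    *,
    require_parent_hom_poly: bool = True,
) -> pd.DataFrame:
    """Union of per-platform SNP tables keyed by locus.

    Each input frame carries chrom, pos, ref, alt and one genotype column per
    sample (allele-pair strings, './.' allowed). Conflicting genotypes across
    platforms resolve by majority; ties drop the locus (logged). Loci whose
    allele pairs are incompatible across platforms are dropped (logged).
    When ``require_parent_hom_poly`` (the table's defining filter), only loci
    where both parents are homozygous and different are kept.
    """
    frames = []
    for platform, frame in snp_sets.items():
        f = frame[["chrom", "pos", "ref", "alt", *samples]].copy()
        f["platform"] = platform
        frames.append(f)
    if not frames:
        return pd.DataFrame(columns=["chrom", "pos", "ref", "alt", "platforms", *samples])
    merged = pd.concat(frames, ignore_index=True)
    rows = []
    n_allele_drop = 0
    n_tie_drop = 0
    for (chrom, pos), grp in merged.groupby(["chrom", "pos"], sort=True):
        allele_sets = {frozenset((r, a)) for r, a in zip(grp.ref, grp.alt)}
        if len(allele_sets) > 1:
            n_allele_drop += 1
            continue
        row = {
            "chrom": chrom,
            "pos": pos,
            "ref": grp.ref.iloc[0],
            "alt": grp.alt.iloc[0],
            "platforms": "+".join(sorted(set(grp.platform))),
        }
        tie = False
        for s in samples:
            vals = grp[s][grp[s] != "./."]
            if len(vals) == 0:
                row[s] = "./."
                continue
            top = vals.value_counts()
            if len(top) > 1 and top.iloc[0] == top.iloc[1]:
                tie = True
                break
            row[s] = top.index[0]
        if tie:
            n_tie_drop += 1
            continue
        rows.append(row)
    if n_allele_drop:
        logger.info("dropped %d loci with incompatible allele pairs", n_allele_drop)
    if n_tie_drop:
        logger.info("dropped %d loci with tied genotype conflicts", n_tie_drop)
    table = pd.DataFrame(rows, columns=["chrom", "pos", "ref", "alt", "platforms", *samples])
    if require_parent_hom_poly and len(table):
        p1, p2 = samples[0], samples[1]
        ok = (
            (table[p1] != "./.")
            & (table[p2] != "./.")
            & table[p1].map(_is_hom)
            & table[p2].map(_is_hom)
            & (table[p1] != table[p2])
        )
        table = table[ok].reset_index(drop=True)
    return table


def filter_ril_polymorphic(
    table: pd.DataFrame, ril_pair: tuple[str, str], parents: tuple[str, str] = ("P1", "P2")
) -> pd.DataFrame:
    """Qualifying SNPs: both sisters homozygous and different from each other.

    Adds a ``phase`` column: 0 when the first sister carries the first
    parent's allele, 1 when reversed, -1 when the sister alleles do not match
    the parental alleles (kept but phase-isolated).
    """
    l1, l2 = ril_pair
    p1, p2 = parents
    t = table
    ok = (
        (t[l1] != "./.")
        & (t[l2] != "./.")
        & t[l1].map(_is_hom)
        & t[l2].map(_is_hom)
        & (t[l1] != t[l2])
    )
    out = t[ok].copy()
    if len(out) == 0:
        out["phase"] = pd.Series(dtype=int)
        return out
    phase = np.where(
        (out[l1] == out[p1]) & (out[l2] == out[p2]),
        0,
        np.where((out[l1] == out[p2]) & (out[l2] == out[p1]), 1, -1),
    )
    out["phase"] = phase
    return out.sort_values(["chrom", "pos"], kind="stable").reset_index(drop=True)


@dataclass
class PolymorphicRegion:
    """Run of phase-consistent qualifying SNPs between two sister lines."""

    chrom: str
    start: int
    end: int
    n_snps: int
    ril_pair: str
    phase: int

    @property
    def origin_first_sister(self) -> str:
        return {0: "P1", 1: "P2"}.get(self.phase, "unresolved")


def call_regions(
    qualifying_snps: pd.DataFrame,
    merge_distance: int,
    ril_pair: str = "",
) -> list[PolymorphicRegion]:
    """Merge consecutive qualifying SNPs into polymorphic regions.

    SNPs on one chromosome join one region while the gap to the previous SNP
    is <= ``merge_distance`` and the sister-origin phase is unchanged; a
    phase flip always starts a new region so each region represents a single
    origin contrast. The region span runs from its first to one past its
    last SNP.
    """
    regions: list[PolymorphicRegion] = []
    snps = qualifying_snps.sort_values(["chrom", "pos"], kind="stable")
    for chrom, grp in snps.groupby("chrom", sort=True):
        pos = grp.pos.to_numpy()
        phase = grp.phase.to_numpy() if "phase" in grp.columns else np.zeros(len(grp), int)
        start_i = 0
        for i in range(1, len(pos) + 1):
            if (
                i == len(pos)
                or pos[i] - pos[i - 1] > merge_distance
                or phase[i] != phase[i - 1]
            ):
                regions.append(
                    PolymorphicRegion(
                        chrom=chrom,
                        start=int(pos[start_i]),
                        end=int(pos[i - 1]) + 1,
                        n_snps=i - start_i,
                        ril_pair=ril_pair,
                        phase=int(phase[start_i]),
                    )
                )
                start_i = i
    return regions


def regions_to_frame(regions: list[PolymorphicRegion]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_snps": r.n_snps,
                "ril_pair": r.ril_pair,
                "phase": r.phase,
            }
            for r in regions
        ],
        columns=["chrom", "start", "end", "n_snps", "ril_pair", "phase"],
    )


def annotate_regions(
    regions: list[PolymorphicRegion],
    gene_models: pd.DataFrame,
    deg_list: set[str] | list[str],
    nod_ortholog_list: set[str] | list[str],
) -> pd.DataFrame:
    """Attach overlapping candidate genes with DEG / nodulation-ortholog labels.

    Returns one row per region with ``candidate_genes`` (list of
    (gene_id, label) pairs, label in {DEG, nodulation-ortholog, both}) and
    summary counts.
    """
    deg = set(deg_list)
    nod = set(nod_ortholog_list)
    trees: dict[str, IntervalTree] = {}
    for gene in gene_models.itertuples(index=False):
        trees.setdefault(gene.chrom, IntervalTree()).addi(
            gene.start, gene.end, gene.gene_id
        )
    rows = []
    for r in regions:
        genes = []
        tree = trees.get(r.chrom)
        if tree is not None:
            for iv in sorted(tree.overlap(r.start, r.end)):
                gid = iv.data
                is_deg = gid in deg
                is_nod = gid in nod
                if not (is_deg or is_nod):
                    continue
                label = "both" if (is_deg and is_nod) else ("DEG" if is_deg else "nodulation-ortholog")
                genes.append((gid, label))
        rows.append(
            {
                "chrom": r.chrom,
                "start": r.start,
                "end": r.end,
                "n_snps": r.n_snps,
                "ril_pair": r.ril_pair,
                "phase": r.phase,
                "candidate_genes": genes,
                "n_deg": sum(1 for _, lab in genes if lab in ("DEG", "both")),
                "n_nod": sum(1 for _, lab in genes if lab in ("nodulation-ortholog", "both")),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "start",
            "end",
            "n_snps",
            "ril_pair",
            "phase",
            "candidate_genes",
            "n_deg",
            "n_nod",
        ],
    )


def write_regions_bed(regions: list[PolymorphicRegion], path) -> None:
    """Regions as BED6 (name = pair, score = n_snps, strand by phase)."""
    frame = regions_to_frame(regions)
    bed = pd.DataFrame(
        {
            "chrom": frame.chrom,
            "start": frame.start,
            "end": frame.end,
            "name": frame.ril_pair.replace("", "pair"),
            "score": frame.n_snps,
            "strand": np.where(frame.phase == 0, "+", "-"),
        }
    )
    bed.to_csv(path, sep="\t", index=False, header=False)


def read_regions_bed(path, ril_pair: str = "") -> list[PolymorphicRegion]:
    bed = pd.read_csv(
        path, sep="\t", names=["chrom", "start", "end", "name", "score", "strand"]
    )
    return [
        PolymorphicRegion(
            chrom=r.chrom,
            start=int(r.start),
            end=int(r.end),
            n_snps=int(r.score),
            ril_pair=ril_pair or r.name,
            phase=0 if r.strand == "+" else 1,
        )
        for r in bed.itertuples(index=False)
    ]


def genotype_matrix(
    table: pd.DataFrame, lines: tuple[str, ...], parents: tuple[str, str] = ("P1", "P2")
) -> pd.DataFrame:
    """Per-SNP parental-origin matrix for graphical-genotype plotting.

    Values: 'P1', 'P2', 'HET', or '.' when a line's genotype is missing or
    matches neither parent.
    """
    p1, p2 = parents
    out = table[["chrom", "pos"]].copy()
    for line in lines:
        vals = []
        for gt, g1, g2 in zip(table[line], table[p1], table[p2]):
            if gt == "./.":
                vals.append(".")
            elif gt == g1:
                vals.append("P1")
            elif gt == g2:
                vals.append("P2")
            elif set(gt.split("/")) == set(g1.split("/")) | set(g2.split("/")) - (
                set(g1.split("/")) & set(g2.split("/"))
            ):
                vals.append("HET")
            else:
                vals.append(".")
        out[line] = vals
    return out
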