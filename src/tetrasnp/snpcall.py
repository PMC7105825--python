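"""Genotype calling and homoeolog-aware SNP filtering (pipelines M1-M5).

The five pipelines combine a reference strategy, a read-retention rule and a
filter stack:

====  =========  =========  ===========================================
id    reference  retention  filters
====  =========  =========  ===========================================
M1    A/B        overall    anchor (homoeolog-diagnostic sites) + depth
M2    A+B        unique     depth only
M3    A+B        unique     anchor + depth
M4    A/B        overall    read(-pair) haplotypes
M5    A+B        unique     read(-pair) haplotypes
====  =========  =========  ===========================================

Depth rules: a heterozygous genotype needs at least ``het_min`` (2) reads on
each allele; a homozygous genotype needs at least ``hom_min`` (4) reads on the
majority allele with the minor allele below ``het_min``. The heterozygous rule
takes precedence where both could apply.

The anchor filter operationalises using homoeologous SNPs as anchors: reads
are partitioned by the allele they carry at nearby homoeolog-diagnostic
sites, and a candidate is kept as allelic only if its variation is confined
to exactly one partition (one subgenome). The haplotype filter clusters
read(-pair)s by the flanking variable sites they share and calls a sample's
allele only inside a single haplotype background, emitting exclusively
homozygous inter-sample differences. A machine-learning rescoring step has no
desk-scale mechanism here and is a declared no-op pass-through.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import BASES, Genome
from .simcore import ReadSet
from . import subalign

HOM_MIN = 4
HET_MIN = 2
DIAG_BAND = (0.2, 0.8)
DIAG_MIN_DEPTH = 4

GT_MISSING = "./."

_PIPELINES = {
    "M1": dict(reference="separate_ab", retention="overall", depth=True, anchor=True, haplotype=False),
    "M2": dict(reference="concatenated_ab", retention="unique", depth=True, anchor=False, haplotype=False),
    "M3": dict(reference="concatenated_ab", retention="unique", depth=True, anchor=True, haplotype=False),
    "M4": dict(reference="separate_ab", retention="overall", depth=False, anchor=False, haplotype=True),
    "M5": dict(reference="concatenated_ab", retention="unique", depth=False, anchor=False, haplotype=True),
}

RECORD_COLUMNS = [
    "chrom",
    "pos",
    "ref",
    "alt",
    "sample1",
    "sample2",
    "gt1",
    "gt2",
    "zygosity",
    "pipeline",
    "anchored",
]


@dataclass(frozen=True)
class PipelineConfig:
    """One of the five named pipeline rows; construct via :meth:`from_id`."""

    id: str
    reference_mode: str
    retention: str
    use_depth: bool
    use_anchor: bool
    use_haplotype: bool
    snpml: str = "pass-through"

    @classmethod
    def from_id(cls, pipeline_id: str) -> "PipelineConfig":
        if pipeline_id not in _PIPELINES:
            raise ValueError(f"unknown pipeline {pipeline_id!r}; expected M1..M5")
        row = _PIPELINES[pipeline_id]
        return cls(
            id=pipeline_id,
            reference_mode=row["reference"],
            retention=row["retention"],
            use_depth=row["depth"],
            use_anchor=row["anchor"],
            use_haplotype=row["haplotype"],
        )

    @classmethod
    def all_ids(cls) -> tuple[str, ...]:
        return tuple(_PIPELINES)


# ---------------------------------------------------------------------------
# Depth rule
# ---------------------------------------------------------------------------


def call_genotype_depth(
    ref_count: int, alt_count: int, hom_min: int = HOM_MIN, het_min: int = HET_MIN
) -> str:
    """Depth-threshold genotype for one sample at one biallelic site.

    het takes precedence; a homozygous call additionally requires the minor
    allele to stay below ``het_min``.
    """
    if ref_count < 0 or alt_count < 0:
        raise ValueError("negative allele counts")
    if ref_count >= het_min and alt_count >= het_min:
        return "het"
    if ref_count >= hom_min and alt_count < het_min:
        return "hom_ref"
    if alt_count >= hom_min and ref_count < het_min:
        return "hom_alt"
    return "missing"


def _call_genotypes_vec(
    ref_count: np.ndarray, alt_count: np.ndarray, hom_min: int = HOM_MIN, het_min: int = HET_MIN
) -> np.ndarray:
    """Vectorised depth rule; codes 0 hom_ref, 1 het, 2 hom_alt, -1 missing."""
    out = np.full(len(ref_count), -1, dtype=np.int8)
    het = (ref_count >= het_min) & (alt_count >= het_min)
    out[het] = 1
    out[~het & (ref_count >= hom_min) & (alt_count < het_min)] = 0
    out[~het & (alt_count >= hom_min) & (ref_count < het_min)] = 2
    return out


# ---------------------------------------------------------------------------
# Candidate discovery
# ---------------------------------------------------------------------------


def candidate_sites(
    counts_by_sample: dict[str, np.ndarray],
    genome: Genome,
    min_alt: int = HET_MIN,
) -> pd.DataFrame:
    """Sites where any sample shows a non-reference allele >= ``min_alt``.

    Returns one row per candidate with the pooled alternate allele and
    per-sample reference/alternate depths (columns ref_<s>, alt_<s>).
    """
    samples = list(counts_by_sample)
    ref = genome.concat
    G = genome.total_length
    pos_idx = np.arange(G)
    pooled_nonref = None
    masks = []
    for s in samples:
        counts = counts_by_sample[s]
        nonref = counts.copy()
        nonref[ref, pos_idx] = 0
        masks.append(nonref.max(axis=0) >= min_alt)
        pooled_nonref = nonref if pooled_nonref is None else pooled_nonref + nonref
    cand = np.flatnonzero(np.logical_or.reduce(masks))
    if len(cand) == 0:
        cols = {"gpos": [], "chrom": [], "pos": [], "ref": [], "alt": []}
        for s in samples:
            cols[f"ref_{s}"] = []
            cols[f"alt_{s}"] = []
        return pd.DataFrame(cols)
    alt = pooled_nonref[:, cand].argmax(axis=0).astype(np.uint8)
    cidx, local = genome.locate(cand)
    out = pd.DataFrame(
        {
            "gpos": cand,
            "chrom": np.asarray(genome.names, dtype=object)[cidx],
            "pos": local,
            "ref": ref[cand],
            "alt": alt,
        }
    )
    for s in samples:
        counts = counts_by_sample[s]
        out[f"ref_{s}"] = counts[ref[cand], cand]
        out[f"alt_{s}"] = counts[alt, cand]
    return out


def find_diagnostic_sites(
    candidates: pd.DataFrame,
    samples: list[str],
    band: tuple[float, float] = DIAG_BAND,
    min_depth: int = DIAG_MIN_DEPTH,
) -> pd.DataFrame:
    """Flag homoeolog-diagnostic anchor sites among candidates.

    A site is diagnostic iff in EVERY sample both alleles are present at
    balanced depth (alternate-allele fraction within ``band``) with at least
    ``min_depth`` covering reads — the signature of a fixed subgenome
    difference, invariant across samples.
    """
    flag = np.ones(len(candidates), dtype=bool)
    for s in samples:
        ref_c = candidates[f"ref_{s}"].to_numpy(dtype=float)
        alt_c = candidates[f"alt_{s}"].to_numpy(dtype=float)
        depth = ref_c + alt_c
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(depth > 0, alt_c / np.maximum(depth, 1), 0.0)
        flag &= (depth >= min_depth) & (frac >= band[0]) & (frac <= band[1])
    out = candidates.copy()
    out["is_diagnostic"] = flag
    return out


# ---------------------------------------------------------------------------
# Read-backed site table
# ---------------------------------------------------------------------------


def site_read_table(
    alignments: pd.DataFrame,
    reads: ReadSet,
    genome: Genome,
    site_gpos: np.ndarray,
    sample: str,
) -> pd.DataFrame:
    """Per-(site, read) base observations at the given sorted global sites."""
    if len(alignments) == 0 or len(site_gpos) == 0:
        return pd.DataFrame(columns=["gpos", "sample", "frag", "mate", "base"])
    queries = reads.queries()
    length = reads.read_length
    offsets = {name: genome.offset(name) for name in genome.names}
    gstart = alignments.chrom.map(offsets).to_numpy(dtype=np.int64) + alignments.start.to_numpy(
        dtype=np.int64
    )
    lo = np.searchsorted(site_gpos, gstart, side="left")
    hi = np.searchsorted(site_gpos, gstart + length, side="left")
    counts = hi - lo
    total = int(counts.sum())
    if total == 0:
        return pd.DataFrame(columns=["gpos", "sample", "frag", "mate", "base"])
    aln_idx = np.repeat(np.arange(len(alignments)), counts)
    site_idx = np.repeat(lo, counts) + (
        np.arange(total) - np.repeat(np.cumsum(counts) - counts, counts)
    )
    sites = site_gpos[site_idx]
    off = sites - gstart[aln_idx]
    qrow = alignments.qrow.to_numpy()[aln_idx]
    strand = alignments.strand.to_numpy()[aln_idx]
    base = np.where(
        strand == 0,
        queries[qrow, off],
        3 - queries[qrow, length - 1 - off],
    ).astype(np.uint8)
    return pd.DataFrame(
        {
            "gpos": sites,
            "sample": sample,
            "frag": alignments.read_id.to_numpy()[aln_idx],
            "mate": alignments.mate.to_numpy()[aln_idx],
            "base": base,
        }
    )


# ---------------------------------------------------------------------------
# Anchor filter
# ---------------------------------------------------------------------------


def anchor_filter(
    candidates: pd.DataFrame,
    table: pd.DataFrame,
    window: int,
    het_min: int = HET_MIN,
) -> pd.DataFrame:
    """Retain candidates whose variation is confined to one read partition.

    Reads are assigned to subgenome partitions by majority vote over the
    diagnostic alleles they cover; a candidate within ``window`` of at least
    one diagnostic site is retained iff exactly one partition carries both of
    its alleles at >= ``het_min``. Candidates with no diagnostic site in
    reach pass unfiltered with ``anchored = False``.
    """
    cand = candidates[~candidates.is_diagnostic].copy()
    diag = candidates[candidates.is_diagnostic]
    if len(cand) == 0:
        cand["anchored"] = pd.Series(dtype=bool)
        cand["retained"] = pd.Series(dtype=bool)
        return cand
    if len(diag) == 0 or len(table) == 0:
        cand["anchored"] = False
        cand["retained"] = True
        return cand

    diag_pos = diag.gpos.to_numpy()
    # anchored = a diagnostic site within the window (same chromosome; the
    # window never exceeds a read span so a cross-chromosome match cannot
    # share covering reads and is harmless)
    idx = np.searchsorted(diag_pos, cand.gpos.to_numpy())
    left = np.abs(diag_pos[np.clip(idx - 1, 0, len(diag_pos) - 1)] - cand.gpos.to_numpy())
    right = np.abs(diag_pos[np.clip(idx, 0, len(diag_pos) - 1)] - cand.gpos.to_numpy())
    anchored = np.minimum(left, right) <= window
    cand["anchored"] = anchored

    # per-read partition vote over covered diagnostic alleles
    diag_alleles = diag[["gpos", "ref", "alt"]].rename(
        columns={"ref": "diag_ref", "alt": "diag_alt"}
    )
    dtab = table.merge(diag_alleles, on="gpos", how="inner")
    dtab = dtab[(dtab.base == dtab.diag_ref) | (dtab.base == dtab.diag_alt)]
    dtab["vote"] = (dtab.base == dtab.diag_alt).astype(float)
    votes = dtab.groupby(["sample", "frag", "mate"], sort=False).vote.mean()
    partition = (votes >= 0.5).astype(np.int8).rename("partition")

    ctab = table[table.gpos.isin(set(cand.gpos))].merge(
        partition.reset_index(), on=["sample", "frag", "mate"], how="inner"
    )
    allele_map = cand.set_index("gpos")[["ref", "alt"]]
    ctab = ctab.merge(allele_map, left_on="gpos", right_index=True)
    ctab["is_ref"] = (ctab.base == ctab.ref).astype(np.int64)
    ctab["is_alt"] = (ctab.base == ctab.alt).astype(np.int64)
    per_part = ctab.groupby(["gpos", "partition"], sort=False)[["is_ref", "is_alt"]].sum()
    var_part = (per_part.is_ref >= het_min) & (per_part.is_alt >= het_min)
    n_var_map = var_part.groupby(level="gpos").sum()
    n_var = cand.gpos.map(n_var_map).fillna(0).astype(int)
    cand["retained"] = np.where(anchored, n_var == 1, True)
    return cand


# ---------------------------------------------------------------------------
# Haplotype filter
# ---------------------------------------------------------------------------


def haplotype_filter(
    candidates: pd.DataFrame,
    table: pd.DataFrame,
    samples: tuple[str, str],
    paired: bool,
    hom_min: int = HOM_MIN,
    purity: float = 0.9,
) -> pd.DataFrame:
    """Haplotype-based homozygous SNP discovery between two samples.

    Read units (read pairs when ``paired`` — the long-range span — single
    reads otherwise) are first assigned to subgenome haplotype partitions by
    majority vote over the homoeolog-diagnostic alleles they carry; units
    reaching no diagnostic site form their own unanchored partition. At each
    candidate, a sample's allele is called within a partition only when it
    has >= ``hom_min`` consistent units and >= ``purity`` agreement. A
    candidate is emitted (homozygous only) iff the partitions where both
    samples are called show exactly one differing allele pair — variation
    between samples inside one subgenome background. Candidates whose
    alleles separate the partitions themselves (the homoeologous signature)
    or that stay mixed within a sample produce no call.
    """
    if len(candidates) == 0 or len(table) == 0:
        return pd.DataFrame(
            columns=["gpos", "chrom", "pos", "ref", "alt", "allele1", "allele2"]
        )

    # pre-screen: skip candidates that look like invariant balanced
    # homoeolog sites in both samples (identical majority, similar balance)
    s1, s2 = samples
    r1 = candidates[f"ref_{s1}"].to_numpy(dtype=float)
    a1 = candidates[f"alt_{s1}"].to_numpy(dtype=float)
    r2 = candidates[f"ref_{s2}"].to_numpy(dtype=float)
    a2 = candidates[f"alt_{s2}"].to_numpy(dtype=float)
    with np.errstate(invalid="ignore", divide="ignore"):
        f1 = np.where(r1 + a1 > 0, a1 / np.maximum(r1 + a1, 1), 0.0)
        f2 = np.where(r2 + a2 > 0, a2 / np.maximum(r2 + a2, 1), 0.0)
    same_majority = (f1 >= 0.5) == (f2 >= 0.5)
    balanced_invariant = (
        same_majority
        & (np.abs(f1 - f2) < 0.25)
        & (f1 > 0.1)
        & (f1 < 0.9)
        & (f2 > 0.1)
        & (f2 < 0.9)
    )
    skip = balanced_invariant
    if "is_diagnostic" in candidates.columns:
        skip = skip | candidates.is_diagnostic.to_numpy()
    todo = candidates[~skip]
    if len(todo) == 0:
        return pd.DataFrame(
            columns=["gpos", "chrom", "pos", "ref", "alt", "allele1", "allele2"]
        )

    unit_cols = ["sample", "frag"] if paired else ["sample", "frag", "mate"]
    t = table
    # collapse duplicate observations within a unit at one site; conflicting
    # mate observations (mate overlap + sequencing error) drop the site
    obs = (
        t.groupby([*unit_cols, "gpos"], sort=False)
        .base.agg(["nunique", "first"])
        .reset_index()
    )
    obs = obs[obs["nunique"] == 1].rename(columns={"first": "base"})

    # subgenome partition per unit: majority vote over diagnostic alleles
    if "is_diagnostic" in candidates.columns and candidates.is_diagnostic.any():
        diag = candidates[candidates.is_diagnostic][["gpos", "ref", "alt"]].rename(
            columns={"ref": "diag_ref", "alt": "diag_alt"}
        )
        dtab = obs.merge(diag, on="gpos", how="inner")
        dtab = dtab[(dtab.base == dtab.diag_ref) | (dtab.base == dtab.diag_alt)]
        dtab["vote"] = (dtab.base == dtab.diag_alt).astype(float)
        votes = dtab.groupby(unit_cols, sort=False).vote.mean()
        partition = (votes >= 0.5).astype(np.int8).rename("partition").reset_index()
    else:
        partition = None

    todo_set = todo[["gpos", "chrom", "pos", "ref", "alt"]]
    ctab = obs.merge(todo_set[["gpos"]], on="gpos", how="inner")
    if partition is not None:
        ctab = ctab.merge(partition, on=unit_cols, how="left")
        ctab["partition"] = ctab.partition.fillna(-1).astype(np.int8)
    else:
        ctab["partition"] = np.int8(0)

    # per (site, partition, sample): dominant base, its count, total units
    grp = (
        ctab.groupby(["gpos", "partition", "sample", "base"], sort=True)
        .size()
        .rename("n")
        .reset_index()
    )
    totals = grp.groupby(["gpos", "partition", "sample"], sort=False).n.transform("sum")
    grp["total"] = totals
    top = grp.sort_values("n", kind="stable").drop_duplicates(
        ["gpos", "partition", "sample"], keep="last"
    )
    called = top[(top.n >= hom_min) & (top.n / top.total >= purity)]

    s1, s2 = samples
    out_rows = []
    meta = todo_set.set_index("gpos")
    for gpos, site_calls in called.groupby("gpos", sort=True):
        pair_calls: set[tuple[int, int]] = set()
        for _, part in site_calls.groupby("partition", sort=False):
            alleles = dict(zip(part["sample"], part.base))
            if s1 in alleles and s2 in alleles and alleles[s1] != alleles[s2]:
                pair_calls.add((int(alleles[s1]), int(alleles[s2])))
        if len(pair_calls) == 1:
            a_1, a_2 = pair_calls.pop()
            row = meta.loc[gpos]
            out_rows.append(
                {
                    "gpos": int(gpos),
                    "chrom": row.chrom,
                    "pos": int(row.pos),
                    "ref": int(row.ref),
                    "alt": int(row.alt),
                    "allele1": a_1,
                    "allele2": a_2,
                }
            )
    return pd.DataFrame(
        out_rows, columns=["gpos", "chrom", "pos", "ref", "alt", "allele1", "allele2"]
    )


# ---------------------------------------------------------------------------
# Pipeline composition
# ---------------------------------------------------------------------------


def _gt_string(a1: int, a2: int) -> str:
    x, y = sorted((int(a1), int(a2)))
    return f"{chr(BASES[x])}/{chr(BASES[y])}"


def _depth_records(
    candidates: pd.DataFrame,
    samples: tuple[str, str],
    pipeline_id: str,
    hom_min: int,
    het_min: int,
) -> pd.DataFrame:
    s1, s2 = samples
    g1 = _call_genotypes_vec(
        candidates[f"ref_{s1}"].to_numpy(),
        candidates[f"alt_{s1}"].to_numpy(),
        hom_min,
        het_min,
    )
    g2 = _call_genotypes_vec(
        candidates[f"ref_{s2}"].to_numpy(),
        candidates[f"alt_{s2}"].to_numpy(),
        hom_min,
        het_min,
    )
    keep = (g1 >= 0) & (g2 >= 0) & (g1 != g2)
    cand = candidates[keep]
    g1k, g2k = g1[keep], g2[keep]
    rows = []
    anchored = cand.anchored.to_numpy() if "anchored" in cand.columns else np.zeros(len(cand), bool)
    for i, c in enumerate(cand.itertuples(index=False)):
        pair1 = {0: (c.ref, c.ref), 1: (c.ref, c.alt), 2: (c.alt, c.alt)}[int(g1k[i])]
        pair2 = {0: (c.ref, c.ref), 1: (c.ref, c.alt), 2: (c.alt, c.alt)}[int(g2k[i])]
        zyg = "heterozygous" if 1 in (g1k[i], g2k[i]) else "homozygous"
        rows.append(
            {
                "chrom": c.chrom,
                "pos": int(c.pos),
                "ref": chr(BASES[int(c.ref)]),
                "alt": chr(BASES[int(c.alt)]),
                "sample1": s1,
                "sample2": s2,
                "gt1": _gt_string(*pair1),
                "gt2": _gt_string(*pair2),
                "zygosity": zyg,
                "pipeline": pipeline_id,
                "anchored": bool(anchored[i]),
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _haplotype_records(
    hap_calls: pd.DataFrame, samples: tuple[str, str], pipeline_id: str
) -> pd.DataFrame:
    rows = []
    for c in hap_calls.itertuples(index=False):
        rows.append(
            {
                "chrom": c.chrom,
                "pos": int(c.pos),
                "ref": chr(BASES[int(c.ref)]),
                "alt": chr(BASES[int(c.alt)]),
                "sample1": samples[0],
                "sample2": samples[1],
                "gt1": _gt_string(c.allele1, c.allele1),
                "gt2": _gt_string(c.allele2, c.allele2),
                "zygosity": "homozygous",
                "pipeline": pipeline_id,
                "anchored": True,
            }
        )
    return pd.DataFrame(rows, columns=RECORD_COLUMNS)


def _dedupe_homoeolog_copies(records: pd.DataFrame) -> pd.DataFrame:
    """Drop B-reference duplicates of A-reference records at partner loci.

    With co-linear subgenomes the separate-reference pipelines can rediscover
    one allelic SNP on both references at the same coordinate; the A-copy is
    kept when alleles and genotypes agree.
    """
    if len(records) == 0:
        return records
    key_cols = ["pos", "gt1", "gt2"]
    a_rec = records[records.chrom.str.startswith("A")]
    b_rec = records[records.chrom.str.startswith("B")]
    if len(a_rec) == 0 or len(b_rec) == 0:
        return records
    a_keys = set(
        zip(a_rec.chrom.str[1:], *(a_rec[c] for c in key_cols))
    )
    drop = [
        (chrom[1:],) + tuple(row)
        in a_keys
        for chrom, row in zip(b_rec.chrom, zip(*(b_rec[c] for c in key_cols)))
    ]
    b_keep = b_rec[~np.array(drop, dtype=bool)]
    return pd.concat([a_rec, b_keep], ignore_index=True)


def run_pipeline(
    pipeline: str | PipelineConfig,
    readsets: dict[str, ReadSet],
    genomes: tuple[Genome, Genome],
    *,
    samples: tuple[str, str] | None = None,
    hom_min: int = HOM_MIN,
    het_min: int = HET_MIN,
    indexes: dict[str, "object"] | None = None,
    alignments: dict[str, pd.DataFrame] | None = None,
) -> pd.DataFrame:
    """Compose align -> pileup -> discovery -> filters per the pipeline row.

    ``readsets`` maps sample name to its reads; exactly two samples are
    compared (defaults to the readset order). Precomputed ``alignments``
    (sample -> frame from :func:`tetrasnp.subalign.align_reads` in the
    matching mode) may be supplied to amortise across pipelines.
    """
    config = pipeline if isinstance(pipeline, PipelineConfig) else PipelineConfig.from_id(pipeline)
    samples = samples or tuple(readsets)[:2]
    s1, s2 = samples
    mode = config.reference_mode
    aln = dict(alignments) if alignments else {}
    for s in samples:
        if s not in aln:
            aln[s] = subalign.align_reads(readsets[s], genomes, mode, indexes=indexes)

    refs: list[tuple[str, Genome]]
    if mode == "separate_ab":
        refs = [("A", genomes[0]), ("B", genomes[1])]
    else:
        refs = [("AB", Genome.concatenate(*genomes))]

    all_records = []
    for ref_tag, ref_genome in refs:
        counts = {}
        sub_aln = {}
        for s in samples:
            sub = aln[s][aln[s].ref == ref_tag] if "ref" in aln[s].columns else aln[s]
            sub_aln[s] = sub
            counts[s] = subalign.pileup(sub, readsets[s], ref_genome)
        cand = candidate_sites(counts, ref_genome, min_alt=het_min)
        if len(cand) == 0:
            continue
        cand = find_diagnostic_sites(cand, list(samples))
        sites = cand.gpos.to_numpy()
        table = pd.concat(
            [
                site_read_table(sub_aln[s], readsets[s], ref_genome, sites, s)
                for s in samples
            ],
            ignore_index=True,
        )
        read_len = readsets[s1].read_length
        if config.use_haplotype:
            calls = haplotype_filter(
                cand,
                table,
                samples,
                readsets[s1].paired,
                hom_min=hom_min,
            )
            all_records.append(_haplotype_records(calls, samples, config.id))
        else:
            if config.use_anchor:
                filt = anchor_filter(cand, table, window=read_len, het_min=het_min)
                filt = filt[filt.retained]
            else:
                filt = cand[~cand.is_diagnostic].copy()
                filt["anchored"] = False
            all_records.append(
                _depth_records(filt, samples, config.id, hom_min, het_min)
            )
    if not all_records:
        return pd.DataFrame(columns=RECORD_COLUMNS)
    records = pd.concat(all_records, ignore_index=True)
    if mode == "separate_ab":
        records = _dedupe_homoeolog_copies(records)
    return records.sort_values(["chrom", "pos"], kind="stable", ignore_index=True)


# ---------------------------------------------------------------------------
# Export
# ---------------------------------------------------------------------------


def write_vcf(records: pd.DataFrame, genomes: tuple[Genome, Genome], path) -> None:
    """Two-sample VCF 4.2 with PIPELINE/ZYG/ANCHORED INFO fields."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##INFO=<ID=PIPELINE,Number=1,Type=String,Description="Source pipeline">\n')
        fh.write('##INFO=<ID=ZYG,Number=1,Type=String,Description="Zygosity class">\n')
        fh.write('##INFO=<ID=ANCHORED,Number=0,Type=Flag,Description="Diagnostic anchor nearby">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        for genome in genomes:
            for name in genome.names:
                fh.write(f"##contig=<ID={name},length={genome.length(name)}>\n")
        s1 = records.sample1.iloc[0] if len(records) else "S1"
        s2 = records.sample2.iloc[0] if len(records) else "S2"
        fh.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{s1}\t{s2}\n")
        for r in records.itertuples(index=False):
            alleles = [r.ref, r.alt]

            def gt_code(gt: str) -> str:
                a, b = gt.split("/")
                for x in (a, b):
                    if x not in alleles:
                        alleles.append(x)
                return f"{alleles.index(a)}/{alleles.index(b)}"

            gt1, gt2 = gt_code(r.gt1), gt_code(r.gt2)
            alt_field = ",".join(alleles[1:])
            info = f"PIPELINE={r.pipeline};ZYG={r.zygosity}"
            if r.anchored:
                info += ";ANCHORED"
            fh.write(
                f"{r.chrom}\t{r.pos + 1}\t.\t{r.ref}\t{alt_field}\t.\tPASS\t{info}\tGT\t{gt1}\t{gt2}\n"
            )


def zygosity_summary(records_by_pipeline: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """Flat per-pipeline totals by zygosity class (Table-2-style accounting)."""
    rows = []
    for pid, rec in records_by_pipeline.items():
        rows.append(
            {
                "pipeline": pid,
                "total": len(rec),
                "heterozygous": int((rec.zygosity == "heterozygous").sum()),
                "homozygous": int((rec.zygosity == "homozygous").sum()),
            }
        )
    return pd.DataFrame(rows)
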