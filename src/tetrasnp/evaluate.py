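"""Truth-based evaluation of simulated runs.

These helpers compare pipeline outputs against the generator's ground truth:
precision/recall of homoeolog-diagnostic site detection, precision of
emitted SNPs, and anchor-filter removal specificity. Recall denominators are
stratified to *assayable* sites — positions where the data actually sampled
both homoeologous alleles at calling depth — since a site whose second
allele never reached the pileup is undetectable in principle.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from ._seq import Genome
from .simcore import ReadSet, TetraploidTruth
from .snpcall import DIAG_MIN_DEPTH


def _origin_depth(
    alignments: pd.DataFrame,
    reads: ReadSet,
    genome: Genome,
    origin_prefix: str,
) -> np.ndarray:
    """Per-base depth restricted to reads whose true origin subgenome matches."""
    depth = np.zeros(genome.total_length + 1, dtype=np.int64)
    if len(alignments) == 0:
        return depth[:-1]
    origins = reads.truth.chrom.str[0].to_numpy()
    sel = alignments[origins[alignments.read_id.to_numpy()] == origin_prefix]
    if len(sel) == 0:
        return depth[:-1]
    offsets = {name: genome.offset(name) for name in genome.names}
    gstart = sel.chrom.map(offsets).to_numpy(dtype=np.int64) + sel.start.to_numpy(
        dtype=np.int64
    )
    gend = gstart + reads.read_length
    np.add.at(depth, gstart, 1)
    np.add.at(depth, gend, -1)
    return np.cumsum(depth)[:-1]


def assayable_homoeolog_gpos(
    truth: TetraploidTruth,
    ref_tag: str,
    ref_genome: Genome,
    alignments_by_sample: dict[str, pd.DataFrame],
    readsets: dict[str, ReadSet],
    min_depth: int = DIAG_MIN_DEPTH,
    interior_band: tuple[float, float] = (0.25, 0.75),
) -> np.ndarray:
    """Truth homoeolog sites on one reference where detection is possible.

    A site is assayable iff, in every sample, reads of both true subgenome
    origins cover it at >= ``min_depth`` each and the cross-origin fraction
    sits safely inside the balanced-depth detection band.
    """
    chrom_col = "chrom_a" if ref_tag == "A" else "chrom_b"
    sites = truth.homoeolog_sites
    gpos = np.array(
        [ref_genome.offset(c) for c in sites[chrom_col]], dtype=np.int64
    ) + sites.pos.to_numpy(dtype=np.int64)
    ok = np.ones(len(gpos), dtype=bool)
    own_prefix = ref_tag
    cross_prefix = "B" if ref_tag == "A" else "A"
    for sample, aln in alignments_by_sample.items():
        own = _origin_depth(aln, readsets[sample], ref_genome, own_prefix)[gpos]
        cross = _origin_depth(aln, readsets[sample], ref_genome, cross_prefix)[gpos]
        total = own + cross
        with np.errstate(invalid="ignore", divide="ignore"):
            frac = np.where(total > 0, cross / np.maximum(total, 1), 0.0)
        ok &= (
            (own >= min_depth)
            & (cross >= min_depth)
            & (frac >= interior_band[0])
            & (frac <= interior_band[1])
        )
    return np.unique(gpos[ok])


def diagnostic_precision_recall(
    truth: TetraploidTruth,
    candidates_by_ref: dict[str, pd.DataFrame],
    ref_genomes: dict[str, Genome],
    alignments_by_ref: dict[str, dict[str, pd.DataFrame]],
    readsets: dict[str, ReadSet],
    min_depth: int = DIAG_MIN_DEPTH,
) -> tuple[float, float]:
    """Pooled precision/recall of diagnostic-site flags vs truth homoeologs."""
    tp = 0
    n_flagged = 0
    n_assayable = 0
    n_recalled = 0
    for ref_tag, cand in candidates_by_ref.items():
        genome = ref_genomes[ref_tag]
        chrom_col = "chrom_a" if ref_tag == "A" else "chrom_b"
        sites = truth.homoeolog_sites
        truth_gpos = set(
            (
                np.array([genome.offset(c) for c in sites[chrom_col]], dtype=np.int64)
                + sites.pos.to_numpy(dtype=np.int64)
            ).tolist()
        )
        flagged = cand[cand.is_diagnostic].gpos.to_numpy()
        n_flagged += len(flagged)
        tp += sum(1 for g in flagged if int(g) in truth_gpos)
        assay = assayable_homoeolog_gpos(
            truth,
            ref_tag,
            genome,
            alignments_by_ref[ref_tag],
            readsets,
            min_depth=min_depth,
        )
        n_assayable += len(assay)
        flagged_set = set(flagged.tolist())
        n_recalled += sum(1 for g in assay if int(g) in flagged_set)
    precision = tp / n_flagged if n_flagged else 0.0
    recall = n_recalled / n_assayable if n_assayable else 0.0
    return precision, recall


def truth_hom_diff_loci(truth: TetraploidTruth) -> set[tuple[str, int]]:
    """Loci where the parents are homozygous for different alleles."""
    s = truth.allelic_sites
    hom_diff = ((s.p1 == 0) & (s.p2 == 2)) | ((s.p1 == 2) & (s.p2 == 0))
    return set(zip(s.chrom[hom_diff], s.pos[hom_diff].astype(int)))


def record_truth_match(
    records: pd.DataFrame,
    truth: TetraploidTruth,
    loci: set[tuple[str, int]] | None = None,
    accept_partner: bool = True,
) -> np.ndarray:
    """Boolean mask: each record lies at a truth locus (or its homoeologous
    partner coordinate, reachable in the separate-reference pipelines)."""
    loci = loci if loci is not None else truth_hom_diff_loci(truth)
    out = np.zeros(len(records), dtype=bool)
    for i, (chrom, pos) in enumerate(zip(records.chrom, records.pos)):
        if (chrom, int(pos)) in loci:
            out[i] = True
        elif accept_partner and (truth.homoeolog_partner(chrom), int(pos)) in loci:
            out[i] = True
    return out


def homozygous_precision(records: pd.DataFrame, truth: TetraploidTruth) -> float | None:
    """Precision of homozygous records against truth parent differences."""
    hom = records[records.zygosity == "homozygous"]
    if len(hom) == 0:
        return None
    return float(record_truth_match(hom, truth).mean())


def homozygous_recall(
    records: pd.DataFrame, truth: TetraploidTruth, loci: set[tuple[str, int]] | None = None
) -> float:
    """Recall of truth homozygous parent differences by a record set."""
    loci = loci if loci is not None else truth_hom_diff_loci(truth)
    if not loci:
        return 0.0
    hom = records[records.zygosity == "homozygous"]
    found = set()
    for chrom, pos in zip(hom.chrom, hom.pos):
        key = (chrom, int(pos))
        pkey = (truth.homoeolog_partner(chrom), int(pos))
        if key in loci:
            found.add(key)
        elif pkey in loci:
            found.add(pkey)
    return len(found) / len(loci)


def anchor_specificity(
    filtered: pd.DataFrame,
    truth: TetraploidTruth,
    ref_tag: str,
    ref_genome: Genome,
) -> float | None:
    """Fraction of anchored truth-homoeologous candidates that were removed."""
    chrom_col = "chrom_a" if ref_tag == "A" else "chrom_b"
    sites = truth.homoeolog_sites
    truth_gpos = set(
        (
            np.array([ref_genome.offset(c) for c in sites[chrom_col]], dtype=np.int64)
            + sites.pos.to_numpy(dtype=np.int64)
        ).tolist()
    )
    anchored = filtered[filtered.anchored]
    is_homoeo = anchored.gpos.apply(lambda g: int(g) in truth_gpos)
    n_homoeo = int(is_homoeo.sum())
    if n_homoeo == 0:
        return None
    removed = int((~anchored.retained[is_homoeo]).sum())
    return removed / n_homoeo
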