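"""Identity-stratified capture target regions, on-target rate, and coverage.

Target regions are probe-hit spans extended 100 bp in both directions and
clipped at chromosome ends. The cutoff ladder 96, 90, 84, 78, 72, 66, 60 on
``identity_score`` corresponds to 80..50% probe-to-genome match; lowering the
cutoff only adds regions, so the region sets are nested by construction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._seq import Genome

CUTOFFS = (96, 90, 84, 78, 72, 66, 60)
EXTENSION = 100


@dataclass
class TargetRegionSet:
    """Extended probe-hit regions retained at one identity-score cutoff."""

    cutoff: float
    regions: pd.DataFrame  # chrom, start, end, probe_id, identity_score

    def __len__(self) -> int:
        return len(self.regions)

    def to_bed(self, path) -> None:
        bed = self.regions[["chrom", "start", "end", "probe_id"]].copy()
        bed["score"] = self.regions.identity_score.round(2)
        bed.to_csv(path, sep="\t", index=False, header=False)


@dataclass
class CoverageSummary:
    """Per-cutoff capture summary over a target region set."""

    cutoff: float
    n_regions: int
    n_regions_covered: int
    pct_regions_covered: float
    on_target_rate: float
    mean_depth: float


def build_target_regions(
    hits: pd.DataFrame,
    cutoff: float,
    genome: Genome,
    extension: int = EXTENSION,
) -> TargetRegionSet:
    """One region per hit with identity_score >= cutoff, extended and clipped."""
    keep = hits[hits.identity_score >= cutoff].copy()
    lengths = {name: genome.length(name) for name in genome.names}
    keep["start"] = np.maximum(keep.start - extension, 0)
    keep["end"] = np.minimum(keep.end + extension, keep.chrom.map(lengths))
    regions = keep[["chrom", "start", "end", "probe_id", "identity_score"]]
    regions = regions.sort_values(
        ["chrom", "start", "end", "probe_id"], kind="stable"
    ).reset_index(drop=True)
    return TargetRegionSet(cutoff=cutoff, regions=regions)


def _percentage(numerator: int, denominator: int) -> float:
    """Integer-count percentage, rounded half-up to 2 decimals."""
    if denominator == 0:
        return 0.0
    import decimal

    frac = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
    return float(frac.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


def coverage_summary(alignments: pd.DataFrame, region_set: TargetRegionSet) -> CoverageSummary:
    """On-target rate, covered-region fraction and mean depth.

    A read is on-target iff its alignment interval overlaps any region by
    at least 1 bp; a region is covered iff at least one read overlaps it;
    mean depth is the mean over regions of per-base depth averaged within
    the region. Empty alignments give zero rates, not an error.
    """
    regions = region_set.regions.reset_index(drop=True)
    n_regions = len(regions)
    if n_regions == 0:
        return CoverageSummary(region_set.cutoff, 0, 0, 0.0, 0.0, 0.0)
    if len(alignments) == 0:
        return CoverageSummary(region_set.cutoff, n_regions, 0, 0.0, 0.0, 0.0)

    covered = np.zeros(n_regions, dtype=bool)
    n_on_target = 0
    mean_region_depth = np.zeros(n_regions, dtype=np.float64)
    aln_by_chrom = dict(tuple(alignments.groupby("chrom", sort=False)))
    for chrom, reg_grp in regions.groupby("chrom", sort=False):
        ridx = reg_grp.index.to_numpy()
        rs = reg_grp.start.to_numpy(dtype=np.int64)
        re_ = reg_grp.end.to_numpy(dtype=np.int64)
        aln = aln_by_chrom.get(chrom)
        if aln is None or len(aln) == 0:
            continue
        a_start = aln.start.to_numpy(dtype=np.int64)
        a_end = aln.end.to_numpy(dtype=np.int64)

        # on-target reads: overlap >= 1 bp with the merged region union
        m_start, m_end = _merge_intervals(rs, re_)
        prev = np.searchsorted(m_start, a_end, side="left") - 1
        hits_union = (prev >= 0) & (m_end[np.clip(prev, 0, None)] > a_start)
        n_on_target += int(hits_union.sum())

        # covered regions: overlap with the merged alignment union
        u_start, u_end = _merge_intervals(a_start, a_end)
        prev = np.searchsorted(u_start, re_, side="left") - 1
        covered[ridx] = (prev >= 0) & (u_end[np.clip(prev, 0, None)] > rs)

        # mean per-base depth within each region via a prefix-sum of depth
        span = int(max(re_.max(), a_end.max())) + 1
        diff = np.zeros(span + 1, dtype=np.int64)
        np.add.at(diff, a_start, 1)
        np.add.at(diff, a_end, -1)
        depth = np.cumsum(diff[:-1])
        prefix = np.concatenate([[0], np.cumsum(depth)])
        mean_region_depth[ridx] = (prefix[re_] - prefix[rs]) / (re_ - rs)
    n_covered = int(covered.sum())
    return CoverageSummary(
        cutoff=region_set.cutoff,
        n_regions=n_regions,
        n_regions_covered=n_covered,
        pct_regions_covered=_percentage(n_covered, n_regions),
        on_target_rate=n_on_target / len(alignments),
        mean_depth=float(mean_region_depth.mean()),
    )


def _merge_intervals(start: np.ndarray, end: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Union of half-open intervals as sorted disjoint (start, end) arrays."""
    order = np.argsort(start, kind="stable")
    s, e = start[order], end[order]
    running_max = np.maximum.accumulate(e)
    new_block = np.concatenate([[True], s[1:] > running_max[:-1]])
    block_id = np.cumsum(new_block) - 1
    out_s = s[new_block]
    out_e = np.maximum.reduceat(e, np.flatnonzero(new_block))
    del block_id
    return out_s, out_e


def cutoff_ladder_summaries(
    hits: pd.DataFrame,
    alignments: pd.DataFrame,
    genome: Genome,
    cutoffs: tuple[float, ...] = CUTOFFS,
) -> pd.DataFrame:
    """Coverage summaries across the full cutoff ladder, one row per cutoff."""
    rows = []
    for cutoff in cutoffs:
        summary = coverage_summary(alignments, build_target_regions(hits, cutoff, genome))
        rows.append(vars(summary))
    return pd.DataFrame(rows)
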