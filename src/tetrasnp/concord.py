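"""Validation of pipeline SNPs against SNP-array genotypes.

A sequencing SNP overlaps the array when an array marker sits at the same
chromosome and position. An overlapped SNP is concordant (validated) iff the
marker is polymorphic between the two compared samples AND the genotypes
match; remaining overlapped loci are partitioned into discordance classes.
All percentages are recomputed from integer counts and rounded half-up to
two decimals.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

DISCORDANCE_CLASSES = (
    "het_seq_hom_array",
    "hom_seq_het_array",
    "allele_mismatch",
    "monomorphic_on_array",
)


def percentage(numerator: int, denominator: int) -> float | None:
    """100 * n / d rounded half-up to 2 decimals; None for a zero denominator."""
    if denominator == 0:
        return None
    frac = decimal.Decimal(100 * numerator) / decimal.Decimal(denominator)
    return float(frac.quantize(decimal.Decimal("0.01"), rounding=decimal.ROUND_HALF_UP))


@dataclass
class OverlapReport:
    """Per-pipeline concordance accounting against the array."""

    pipeline: str
    n_total: int
    n_overlapped: int
    n_concordant: int
    n_overlapped_het: int = 0
    n_overlapped_hom: int = 0
    n_concordant_het: int = 0
    n_concordant_hom: int = 0
    discordance: dict[str, int] = field(default_factory=dict)

    @property
    def concordance_pct(self) -> float | None:
        return percentage(self.n_concordant, self.n_overlapped)

    @property
    def concordance_pct_het(self) -> float | None:
        return percentage(self.n_concordant_het, self.n_overlapped_het)

    @property
    def concordance_pct_hom(self) -> float | None:
        return percentage(self.n_concordant_hom, self.n_overlapped_hom)

    def to_row(self) -> dict:
        row = {
            "pipeline": self.pipeline,
            "n_total": self.n_total,
            "n_overlapped": self.n_overlapped,
            "n_overlapped_het": self.n_overlapped_het,
            "n_overlapped_hom": self.n_overlapped_hom,
            "n_concordant": self.n_concordant,
            "n_concordant_het": self.n_concordant_het,
            "n_concordant_hom": self.n_concordant_hom,
            "concordance_pct": self.concordance_pct,
            "concordance_pct_het": self.concordance_pct_het,
            "concordance_pct_hom": self.concordance_pct_hom,
        }
        for cls in DISCORDANCE_CLASSES:
            row[cls] = self.discordance.get(cls, 0)
        return row


def _is_het(gt: str) -> bool:
    a, b = gt.split("/")
    return a != b


def _poly(gt1: str, gt2: str) -> bool:
    return gt1 != gt2


def overlap_and_score(
    snps: pd.DataFrame,
    array_table: pd.DataFrame,
    samples: tuple[str, str] = ("P1", "P2"),
    pipeline: str | None = None,
) -> tuple[OverlapReport, pd.DataFrame]:
    """Score pipeline SNPs against the array at shared loci.

    ``snps`` needs chrom, pos, gt1, gt2 (allele-pair strings), zygosity;
    ``array_table`` needs chrom, pos plus one genotype column per sample.
    Returns the report and a per-locus frame with a ``status`` column
    (concordant or a discordance class). With no overlapped loci the
    concordance percentage is None (undefined), mirroring dashed table cells.
    """
    pid = pipeline or (snps.pipeline.iloc[0] if "pipeline" in snps.columns and len(snps) else "?")
    s1, s2 = samples
    n_total = len(snps)
    merged = snps.merge(
        array_table[["chrom", "pos", s1, s2]], on=["chrom", "pos"], how="inner"
    )
    # drop loci with missing array genotypes in either sample
    callable_mask = (~merged[s1].isin(["./."])) & (~merged[s2].isin(["./."]))
    merged = merged[callable_mask].reset_index(drop=True)

    status = []
    for r in merged.itertuples(index=False):
        seq_het = _is_het(r.gt1) or _is_het(r.gt2)
        arr_gt1, arr_gt2 = getattr(r, s1), getattr(r, s2)
        arr_poly = _poly(arr_gt1, arr_gt2)
        if arr_poly and r.gt1 == arr_gt1 and r.gt2 == arr_gt2:
            status.append("concordant")
        elif not arr_poly:
            status.append("monomorphic_on_array")
        else:
            arr_het = _is_het(arr_gt1) or _is_het(arr_gt2)
            if seq_het and not arr_het:
                status.append("het_seq_hom_array")
            elif not seq_het and arr_het:
                status.append("hom_seq_het_array")
            else:
                status.append("allele_mismatch")
    merged["status"] = status
    het_mask = merged.zygosity == "heterozygous" if "zygosity" in merged.columns else pd.Series(
        [False] * len(merged)
    )
    conc = merged.status == "concordant"
    report = OverlapReport(
        pipeline=pid,
        n_total=n_total,
        n_overlapped=len(merged),
        n_concordant=int(conc.sum()),
        n_overlapped_het=int(het_mask.sum()),
        n_overlapped_hom=int((~het_mask).sum()) if len(merged) else 0,
        n_concordant_het=int((conc & het_mask).sum()),
        n_concordant_hom=int((conc & ~het_mask).sum()),
        discordance={
            cls: int((merged.status == cls).sum()) for cls in DISCORDANCE_CLASSES
        },
    )
    return report, merged


def monomorphic_fraction(
    array_table: pd.DataFrame,
    pair: tuple[str, str],
    *,
    parents: tuple[str, str] = ("P1", "P2"),
) -> tuple[float | None, int, int]:
    """Fraction of homozygous parental-SNP loci monomorphic within a RIL pair.

    The denominator is the loci where both parents are homozygous and
    polymorphic on the array and both pair members have non-missing
    genotypes; the numerator counts loci where the pair genotypes agree.
    Returns (percentage or None, numerator, denominator).
    """
    l1, l2 = pair
    p1, p2 = parents
    tab = array_table
    hom_poly = (
        (~tab[p1].isin(["./."]))
        & (~tab[p2].isin(["./."]))
        & (tab[p1] != tab[p2])
        & (~tab[p1].map(_is_het))
        & (~tab[p2].map(_is_het))
    )
    tab = tab[hom_poly]
    callable_mask = (~tab[l1].isin(["./."])) & (~tab[l2].isin(["./."]))
    tab = tab[callable_mask]
    denom = len(tab)
    numer = int((tab[l1] == tab[l2]).sum())
    return percentage(numer, denom), numer, denom


def pipeline_overlap(
    set_a: pd.DataFrame, set_b: pd.DataFrame
) -> dict[str, float | int | None]:
    """Shared/unique locus counts between two pipelines' SNP sets.

    Loci are (chrom, pos) pairs. ``pct_a_covered_by_b`` is the percentage of
    A's loci also present in B.
    """
    loci_a = set(zip(set_a.chrom, set_a.pos))
    loci_b = set(zip(set_b.chrom, set_b.pos))
    shared = len(loci_a & loci_b)
    return {
        "n_a": len(loci_a),
        "n_b": len(loci_b),
        "shared": shared,
        "only_a": len(loci_a - loci_b),
        "only_b": len(loci_b - loci_a),
        "pct_a_covered_by_b": percentage(shared, len(loci_a)),
        "pct_b_covered_by_a": percentage(shared, len(loci_b)),
    }


def reports_to_table(reports: list[OverlapReport]) -> pd.DataFrame:
    """Table-2-shaped summary: one row per pipeline."""
    return pd.DataFrame([r.to_row() for r in reports])
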