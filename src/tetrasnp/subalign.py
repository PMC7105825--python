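"""Deterministic ungapped read placement for the two reference strategies.

Two modes mirror the study's Table-1 contrast:

``separate_ab``
    Reads are aligned to the A and B subgenome references independently and
    the best placement per subgenome is kept ("overall" retention) — a read
    from one subgenome may therefore also align, slightly worse, to its
    homoeologous locus on the other reference.
``concatenated_ab``
    Reads are aligned to the concatenated A+B reference and only reads whose
    best placement is strictly better than any alternative are kept
    ("unique" retention, the stand-in for discarding MAPQ-0 / multi-hit
    reads). Mates must additionally land on one chromosome, on opposite
    strands, within the insert window.

Alignment is exact-seed (k = 21) ungapped extension scored by mismatch
count; the mismatch budget is a fraction of read length (default 6%).
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from . import _kmer
from ._seq import Genome
from .simcore import ReadSet

READ_SEED_K = 21
MAX_MISMATCH_RATE = 0.06
INSERT_MIN = 100
INSERT_MAX = 600

ALIGNMENT_COLUMNS = [
    "read_id",
    "mate",
    "qrow",
    "ref",
    "chrom",
    "start",
    "end",
    "strand",
    "mismatches",
    "score",
    "n_equal_best",
]


def _best_alignments(
    hits: _kmer.SearchHits, genome: Genome, length: int
) -> pd.DataFrame:
    """Pick the deterministic best placement per query; count ties."""
    if len(hits) == 0:
        return pd.DataFrame(columns=["qrow", "gstart", "strand", "mismatches", "n_equal_best"])
    # hits are sorted by (qidx, start, strand); re-sort by mismatches first
    order = np.lexsort((hits.strand, hits.start, hits.mismatches, hits.qidx))
    qidx = hits.qidx[order]
    start = hits.start[order]
    strand = hits.strand[order]
    mm = hits.mismatches[order]
    first = np.unique(qidx, return_index=True)[1]
    best_mm = mm[first]
    # ties: runs with the same query and the same (minimal) mismatch count
    same_q = np.repeat(qidx[first], np.diff(np.concatenate([first, [len(qidx)]])))
    is_best = mm == np.repeat(best_mm, np.diff(np.concatenate([first, [len(qidx)]])))
    del same_q
    n_best = np.add.reduceat(is_best.astype(np.int64), first)
    return pd.DataFrame(
        {
            "qrow": qidx[first],
            "gstart": start[first],
            "strand": strand[first],
            "mismatches": best_mm,
            "n_equal_best": n_best,
        }
    )


def _to_frame(
    best: pd.DataFrame, genome: Genome, length: int, ref: str, n_fragments: int
) -> pd.DataFrame:
    cidx, local = genome.locate(best.gstart.to_numpy(dtype=np.int64))
    qrow = best.qrow.to_numpy()
    return pd.DataFrame(
        {
            "read_id": qrow % n_fragments,
            "mate": qrow // n_fragments,
            "qrow": qrow,
            "ref": ref,
            "chrom": np.asarray(genome.names, dtype=object)[cidx],
            "start": local,
            "end": local + length,
            "strand": best.strand.to_numpy(),
            "mismatches": best.mismatches.to_numpy(),
            "score": length - best.mismatches.to_numpy(),
            "n_equal_best": best.n_equal_best.to_numpy(),
        }
    )


def align_reads(
    reads: ReadSet,
    genomes: tuple[Genome, Genome],
    mode: str = "concatenated_ab",
    max_mismatch_rate: float = MAX_MISMATCH_RATE,
    k: int = READ_SEED_K,
    *,
    indexes: dict[str, _kmer.KmerIndex] | None = None,
) -> pd.DataFrame:
    """Align one read set; returns one row per retained alignment.

    ``genomes`` is the (subgenome A, subgenome B) pair. ``indexes`` may carry
    prebuilt k-mer indexes keyed by "A", "B", "AB" to amortise index
    construction across samples. Reads shorter than ``k`` are skipped with a
    warning.
    """
    if mode not in ("separate_ab", "concatenated_ab"):
        raise ValueError(f"unknown mode {mode!r}")
    length = reads.read_length
    if length < k:
        warnings.warn(f"reads of {length} bp are shorter than the {k}-mer seed; skipped")
        return pd.DataFrame(columns=ALIGNMENT_COLUMNS)
    queries = reads.queries()
    max_mm = int(max_mismatch_rate * length)
    n_frag = reads.n_fragments
    indexes = indexes or {}

    if mode == "separate_ab":
        frames = []
        for ref, genome in zip(("A", "B"), genomes):
            index = indexes.get(ref) or _kmer.KmerIndex.build(genome, k)
            hits = _kmer.search(queries, index, max_mm)
            best = _best_alignments(hits, genome, length)
            frames.append(_to_frame(best, genome, length, ref, n_frag))
        out = pd.concat(frames, ignore_index=True)
        return out.sort_values(
            ["read_id", "mate", "ref"], kind="stable", ignore_index=True
        )

    genome = Genome.concatenate(*genomes)
    index = indexes.get("AB") or _kmer.KmerIndex.build(genome, k)
    hits = _kmer.search(queries, index, max_mm)
    best = _best_alignments(hits, genome, length)
    best = best[best.n_equal_best == 1]
    out = _to_frame(best, genome, length, "AB", n_frag)
    if reads.paired:
        out = _concordant_pairs(out)
    return out.sort_values(["read_id", "mate"], kind="stable", ignore_index=True)


def _concordant_pairs(aln: pd.DataFrame) -> pd.DataFrame:
    """Keep pairs with both mates unique, one chromosome, opposite strands,
    and an insert length inside the configured window."""
    m0 = aln[aln.mate == 0][["read_id", "chrom", "start", "end", "strand"]]
    m1 = aln[aln.mate == 1][["read_id", "chrom", "start", "end", "strand"]]
    merged = m0.merge(m1, on="read_id", suffixes=("_0", "_1"))
    if len(merged) == 0:
        return aln.iloc[0:0]
    insert = np.maximum(merged.end_0, merged.end_1) - np.minimum(
        merged.start_0, merged.start_1
    )
    ok = (
        (merged.chrom_0 == merged.chrom_1)
        & (merged.strand_0 != merged.strand_1)
        & (insert >= INSERT_MIN)
        & (insert <= INSERT_MAX)
    )
    keep = set(merged.read_id[ok])
    return aln[aln.read_id.isin(keep)]


def pileup(
    alignments: pd.DataFrame,
    reads: ReadSet,
    genome: Genome,
) -> np.ndarray:
    """Per-base allele counts over the target genome: array (4, total_length).

    Strand is ignored for counting: minus-strand alignments contribute the
    reverse complement of the stored read, i.e. the forward-genome base.
    """
    counts = np.zeros((4, genome.total_length), dtype=np.int32)
    if len(alignments) == 0:
        return counts
    queries = reads.queries()
    length = reads.read_length
    span = np.arange(length, dtype=np.int64)
    offsets = {name: genome.offset(name) for name in genome.names}
    gstart = alignments.chrom.map(offsets).to_numpy(dtype=np.int64) + alignments.start.to_numpy(
        dtype=np.int64
    )
    qrow = alignments.qrow.to_numpy()
    strand = alignments.strand.to_numpy()
    chunk = max(1, 2_000_000 // length)
    for beg in range(0, len(alignments), chunk):
        end = min(beg + chunk, len(alignments))
        q = queries[qrow[beg:end]]
        flip = strand[beg:end] == 1
        if flip.any():
            q = q.copy()
            q[flip] = (3 - q[flip])[:, ::-1]
        gpos = gstart[beg:end, None] + span
        np.add.at(counts, (q.ravel(), gpos.ravel()), 1)
    return counts


def alignments_to_tsv(alignments: pd.DataFrame, path) -> None:
    """SAM-like flat TSV export (read, mate, chrom, pos, mismatches, ties)."""
    alignments.drop(columns=["qrow"]).to_csv(path, sep="\t", index=False)


def unique_fraction(alignments: pd.DataFrame, reads: ReadSet) -> float:
    """Fraction of input mates retained (concatenated/unique mode output)."""
    total = reads.n_reads
    return len(alignments) / total if total else 0.0
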