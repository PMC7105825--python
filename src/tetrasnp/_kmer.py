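"""Exact k-mer indexing and batched ungapped seed-and-extend search.

This is the engine behind both read alignment and probe mapping. K-mers are
packed into integers (base-4 positional code), indexed by sorting, and looked
up with binary search; candidate loci are then verified by full-length
vectorised mismatch counting. The model is strictly ungapped: query length
equals alignment span.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from ._seq import Genome

_VERIFY_CHUNK = 500_000


def pack_kmers(codes: np.ndarray, k: int) -> np.ndarray:
    """Pack every k-mer of a code array into int64 (exact for k <= 26)."""
    if len(codes) < k:
        return np.empty(0, dtype=np.int64)
    powers = 4.0 ** np.arange(k - 1, -1, -1)
    windows = np.lib.stride_tricks.sliding_window_view(codes, k)
    return (windows @ powers).astype(np.int64)


@dataclass
class KmerIndex:
    """Sorted k-mer table over the concatenated genome.

    K-mers spanning a chromosome boundary are excluded, so every hit position
    maps cleanly back to a single chromosome.
    """

    genome: Genome
    k: int
    kmers: np.ndarray  # sorted packed k-mers
    positions: np.ndarray  # global start position of each k-mer, co-sorted

    @classmethod
    def build(cls, genome: Genome, k: int) -> "KmerIndex":
        all_kmers = []
        all_pos = []
        for name in genome.names:
            codes = genome.chroms[name]
            km = pack_kmers(codes, k)
            if len(km):
                all_kmers.append(km)
                all_pos.append(np.arange(len(km), dtype=np.int64) + genome.offset(name))
        if all_kmers:
            kmers = np.concatenate(all_kmers)
            positions = np.concatenate(all_pos)
        else:
            kmers = np.empty(0, dtype=np.int64)
            positions = np.empty(0, dtype=np.int64)
        order = np.argsort(kmers, kind="stable")
        return cls(genome, k, kmers[order], positions[order])

    def lookup(self, query_kmers: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Return (query row index, genome position) for every k-mer match."""
        lo = np.searchsorted(self.kmers, query_kmers, side="left")
        hi = np.searchsorted(self.kmers, query_kmers, side="right")
        counts = hi - lo
        total = int(counts.sum())
        if total == 0:
            return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
        qidx = np.repeat(np.arange(len(query_kmers), dtype=np.int64), counts)
        starts = np.repeat(lo, counts)
        offs = np.arange(total, dtype=np.int64) - np.repeat(
            np.cumsum(counts) - counts, counts
        )
        return qidx, self.positions[starts + offs]


@dataclass
class SearchHits:
    """Flat arrays describing verified ungapped placements of queries."""

    qidx: np.ndarray  # query row
    start: np.ndarray  # global alignment start (forward genome coordinates)
    strand: np.ndarray  # 0 = forward, 1 = query reverse-complemented
    mismatches: np.ndarray

    def __len__(self) -> int:
        return len(self.qidx)


def seed_offsets(length: int, k: int, n_seeds: int) -> np.ndarray:
    """Evenly spread seed start offsets across a query of given length."""
    if length < k:
        return np.empty(0, dtype=np.int64)
    n = max(1, min(n_seeds, length - k + 1))
    return np.unique(np.linspace(0, length - k, n).round().astype(np.int64))


def search(
    queries: np.ndarray,
    index: KmerIndex,
    max_mismatches: int,
    n_seeds: int = 3,
    both_strands: bool = True,
) -> SearchHits:
    """Find all ungapped placements of fixed-length queries with <= max_mismatches.

    Sensitivity is governed by the seed count and the index k: a locus is found
    iff at least one seed k-mer matches it exactly. Results are deduplicated
    and sorted by (query, start, strand); fully deterministic.
    """
    queries = np.ascontiguousarray(queries, dtype=np.uint8)
    n, length = queries.shape
    k = index.k
    offsets = seed_offsets(length, k, n_seeds)
    if len(offsets) == 0 or n == 0:
        e = np.empty(0, dtype=np.int64)
        return SearchHits(e, e, e.astype(np.int8), e)

    genome = index.genome
    bounds = genome.chrom_index_bounds()
    cand_q: list[np.ndarray] = []
    cand_s: list[np.ndarray] = []
    cand_t: list[np.ndarray] = []

    strands = (0, 1) if both_strands else (0,)
    powers = 4.0 ** np.arange(k - 1, -1, -1)
    for strand in strands:
        qs = queries if strand == 0 else (3 - queries)[:, ::-1]
        for off in offsets:
            seed_km = (qs[:, off : off + k] @ powers).astype(np.int64)
            qidx, pos = index.lookup(seed_km)
            if len(qidx) == 0:
                continue
            cand_q.append(qidx)
            cand_s.append(pos - off)
            cand_t.append(np.full(len(qidx), strand, dtype=np.int8))

    if not cand_q:
        e = np.empty(0, dtype=np.int64)
        return SearchHits(e, e, e.astype(np.int8), e)

    qidx = np.concatenate(cand_q)
    start = np.concatenate(cand_s)
    strand_arr = np.concatenate(cand_t)

    # in-bounds within one chromosome
    cidx = np.searchsorted(genome.offsets, start, side="right") - 1
    valid = (start >= 0) & (cidx >= 0) & (cidx < len(bounds))
    cidx = np.clip(cidx, 0, len(bounds) - 1)
    valid &= start + length <= bounds[cidx, 1]
    qidx, start, strand_arr = qidx[valid], start[valid], strand_arr[valid]

    # deduplicate (same locus reachable from several seeds)
    key = (qidx * (genome.total_length + length + 1) + start) * 2 + strand_arr
    _, uniq = np.unique(key, return_index=True)
    qidx, start, strand_arr = qidx[uniq], start[uniq], strand_arr[uniq]

    # verify by full-length mismatch counting, chunked for memory
    concat = genome.concat
    mm = np.empty(len(qidx), dtype=np.int32)
    span = np.arange(length, dtype=np.int64)
    rc = (3 - queries)[:, ::-1]
    for beg in range(0, len(qidx), _VERIFY_CHUNK):
        end = min(beg + _VERIFY_CHUNK, len(qidx))
        seg = concat[start[beg:end, None] + span]
        q = np.where(
            (strand_arr[beg:end] == 0)[:, None],
            queries[qidx[beg:end]],
            rc[qidx[beg:end]],
        )
        mm[beg:end] = (seg != q).sum(axis=1)
    keep = mm <= max_mismatches
    qidx, start, strand_arr, mm = qidx[keep], start[keep], strand_arr[keep], mm[keep]

    order = np.lexsort((strand_arr, start, qidx))
    return SearchHits(qidx[order], start[order], strand_arr[order], mm[order])
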