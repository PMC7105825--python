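"""Sequence encoding helpers and the in-memory genome container.

Sequences are held as numpy uint8 code arrays (A=0, C=1, G=2, T=3) so that
mutation, reverse complement, k-mer packing and mismatch counting are all
vectorised. FASTA round-trips go through Biopython.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

BASES = np.frombuffer(b"ACGT", dtype=np.uint8)

_ENCODE = np.full(256, 255, dtype=np.uint8)
for _i, _b in enumerate(b"ACGT"):
    _ENCODE[_b] = _i
    _ENCODE[_b + 32] = _i  # lower case


def encode(seq: str | bytes) -> np.ndarray:
    """Encode an ACGT string to a uint8 code array (A=0,C=1,G=2,T=3)."""
    raw = np.frombuffer(seq.encode() if isinstance(seq, str) else seq, dtype=np.uint8)
    codes = _ENCODE[raw]
    if (codes == 255).any():
        bad = chr(int(raw[codes == 255][0]))
        raise ValueError(f"non-ACGT character {bad!r} in sequence")
    return codes


def decode(codes: np.ndarray) -> str:
    return BASES[codes].tobytes().decode()


def revcomp(codes: np.ndarray) -> np.ndarray:
    """Reverse complement of a code array (complement is 3 - code)."""
    return (3 - codes)[::-1]


@dataclass
class Genome:
    """Ordered set of chromosomes with a flat concatenated coordinate view.

    ``gpos`` (global position) = chromosome offset + local position; the flat
    view lets alignment and pileup run on single numpy arrays.
    """

    chroms: dict[str, np.ndarray]
    _names: list[str] = field(init=False, repr=False)
    _offsets: np.ndarray = field(init=False, repr=False)
    _concat: np.ndarray = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self._names = list(self.chroms)
        lengths = np.array([len(self.chroms[n]) for n in self._names], dtype=np.int64)
        self._offsets = np.concatenate([[0], np.cumsum(lengths)])
        self._concat = (
            np.concatenate([self.chroms[n] for n in self._names])
            if self._names
            else np.empty(0, dtype=np.uint8)
        )

    @property
    def names(self) -> list[str]:
        return self._names

    @property
    def total_length(self) -> int:
        return int(self._offsets[-1])

    @property
    def concat(self) -> np.ndarray:
        return self._concat

    @property
    def offsets(self) -> np.ndarray:
        return self._offsets

    def length(self, name: str) -> int:
        return len(self.chroms[name])

    def offset(self, name: str) -> int:
        return int(self._offsets[self._names.index(name)])

    def gpos(self, chrom: str, pos) -> np.ndarray | int:
        return self.offset(chrom) + pos

    def locate(self, gpos) -> tuple[np.ndarray, np.ndarray]:
        """Map global positions back to (chrom index array, local pos array)."""
        gpos = np.asarray(gpos, dtype=np.int64)
        idx = np.searchsorted(self._offsets, gpos, side="right") - 1
        return idx, gpos - self._offsets[idx]

    def chrom_index_bounds(self) -> np.ndarray:
        """(n_chrom, 2) array of [start, end) global bounds per chromosome."""
        return np.stack([self._offsets[:-1], self._offsets[1:]], axis=1)

    @classmethod
    def concatenate(cls, *genomes: "Genome") -> "Genome":
        merged: dict[str, np.ndarray] = {}
        for g in genomes:
            for name, seq in g.chroms.items():
                if name in merged:
                    raise ValueError(f"duplicate chromosome name {name!r}")
                merged[name] = seq
        return cls(merged)

    def to_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(decode(seq)), id=name, description="")
            for name, seq in self.chroms.items()
        ]
        SeqIO.write(records, str(path), "fasta")

    @classmethod
    def from_fasta(cls, path: str | Path) -> "Genome":
        chroms = {rec.id: encode(str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")}
        return cls(chroms)
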