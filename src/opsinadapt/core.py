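"""Core sequence containers shared by all analysis stages.

An :class:`Alignment` is a set of equal-length nucleotide sequences with
stable identifiers — the substrate for polymorphism counting, allele
grouping, distance computation and tree building.  :class:`Haplotype`
attaches sample metadata (species, sampling locality, depth) to a single
sequence, mirroring how field samples are recorded.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: IUPAC nucleotide ambiguity codes mapped to the bases they may stand for.
IUPAC_CODES: dict[str, str] = {
    "A": "A", "C": "C", "G": "G", "T": "T",
    "R": "AG", "Y": "CT", "S": "CG", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Biallelic ambiguity codes (heterozygous direct-sequencing calls).
BIALLELIC_CODES = frozenset("RYSWKM")

GAP_CHARS = frozenset("-.")


@dataclass
class Haplotype:
    """A single sequenced haplotype with its sample metadata."""

    id: str
    sequence: str
    species: str = ""
    locality: str = ""
    depth_m: float | None = None

    def __post_init__(self) -> None:
        seq = self.sequence.upper()
        bad = set(seq) - set(IUPAC_CODES) - GAP_CHARS
        if bad:
            raise ValueError(f"haplotype {self.id!r}: invalid characters {sorted(bad)}")
        self.sequence = seq


class Alignment:
    """Equal-length nucleotide sequences with unique identifiers.

    Parameters
    ----------
    ids:
        Sequence identifiers, unique.
    seqs:
        Nucleotide strings, all of identical length.
    """

    def __init__(self, ids: Sequence[str], seqs: Sequence[str]):
        if len(ids) != len(seqs):
            raise ValueError("ids and seqs must have equal length")
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate sequence ids")
        seqs = [s.upper() for s in seqs]
        if seqs:
            L = len(seqs[0])
            if any(len(s) != L for s in seqs):
                raise ValueError("sequences are not aligned (unequal lengths)")
        self.ids: list[str] = list(ids)
        self.seqs: list[str] = seqs

    @property
    def n(self) -> int:
        return len(self.seqs)

    @property
    def length(self) -> int:
        return len(self.seqs[0]) if self.seqs else 0

    def matrix(self) -> np.ndarray:
        """Character matrix of shape ``(n, length)``."""
        if not self.seqs:
            return np.empty((0, 0), dtype="U1")
        joined = "".join(self.seqs).encode("ascii")
        return (np.frombuffer(joined, dtype="S1")
                .reshape(self.n, self.length).astype("U1"))

    def sequence(self, seq_id: str) -> str:
        return self.seqs[self.ids.index(seq_id)]

    def subset(self, keep_ids: Iterable[str]) -> "Alignment":
        keep = list(keep_ids)
        idx = {i: k for k, i in enumerate(self.ids)}
        return Alignment(keep, [self.seqs[idx[i]] for i in keep])

    def drop(self, drop_ids: Iterable[str]) -> "Alignment":
        drop = set(drop_ids)
        keep = [i for i in self.ids if i not in drop]
        return self.subset(keep)

    def __iter__(self):
        return iter(zip(self.ids, self.seqs))

    def __repr__(self) -> str:  # pragma: no cover
        return f"Alignment(n={self.n}, length={self.length})"

    # ------------------------------------------------------------------ I/O

    @classmethod
    def read_fasta(cls, path: str | Path) -> "Alignment":
        records = list(SeqIO.parse(str(path), "fasta"))
        if not records:
            raise ValueError(f"no sequences in {path}")
        return cls([r.id for r in records], [str(r.seq) for r in records])

    def write_fasta(self, path: str | Path) -> None:
        records = [
            SeqRecord(Seq(s), id=i, description="") for i, s in zip(self.ids, self.seqs)
        ]
        SeqIO.write(records, str(path), "fasta")


def hamming(seq1: str, seq2: str, *, pairwise_deletion: bool = True) -> tuple[int, int]:
    """Nucleotide differences between two aligned sequences.

    Returns ``(differences, sites_compared)``.  With ``pairwise_deletion``
    (the default) columns where either sequence carries a gap or any
    ambiguity code are excluded from both counts.
    """
    diffs = 0
    valid = 0
    for a, b in zip(seq1, seq2):
        if pairwise_deletion and (a not in "ACGT" or b not in "ACGT"):
            continue
        valid += 1
        if a != b:
            diffs += 1
    return diffs, valid
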