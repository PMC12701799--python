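"""Multiple sequence alignments: container, FASTA I/O, and summary statistics."""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

__all__ = [
    "MSA",
    "GAP",
    "IUPAC_SETS",
    "read_fasta",
    "write_fasta",
    "count_patterns",
    "gap_fraction",
    "superimpose_gaps",
]

GAP = "-"

# IUPAC nucleotide codes -> compatible base sets (A,C,G,T).  Gap and N are
# fully undetermined for likelihood/parsimony purposes.
IUPAC_SETS: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
    "?": frozenset("ACGT"),
    GAP: frozenset("ACGT"),
}


@dataclass
class MSA:
    """Rectangular DNA alignment over {A,C,G,T,-} plus IUPAC ambiguity codes.

    `data` is an (n_taxa, n_sites) array of single uppercase characters;
    `taxa` are unique ordered labels, one per row.
    """

    taxa: list[str]
    data: np.ndarray  # dtype '<U1', shape (n_taxa, n_sites)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype="<U1")
        if self.data.ndim != 2:
            raise ValueError("MSA data must be a 2-D character matrix")
        if len(self.taxa) != self.data.shape[0]:
            raise ValueError(
                f"{len(self.taxa)} taxa but {self.data.shape[0]} alignment rows"
            )
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxon labels")
        if self.data.shape[1] < 1:
            raise ValueError("alignment has no sites")
        self.data = np.char.upper(self.data)

    @classmethod
    def from_sequences(cls, taxa: Sequence[str], seqs: Sequence[str]) -> "MSA":
        lengths = {len(s) for s in seqs}
        if len(lengths) > 1:
            raise ValueError(f"ragged alignment: row lengths {sorted(lengths)}")
        data = np.array([list(s.upper()) for s in seqs], dtype="<U1")
        return cls(list(taxa), data)

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_sites(self) -> int:
        return self.data.shape[1]

    def sequence(self, taxon: str) -> str:
        return "".join(self.data[self.taxa.index(taxon)])

    def sequences(self) -> list[str]:
        return ["".join(row) for row in self.data]

    def row_order(self, taxa: Sequence[str]) -> "MSA":
        """Reorder rows to the given taxon order."""
        idx = [self.taxa.index(t) for t in taxa]
        return MSA(list(taxa), self.data[idx])

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, MSA):
            return NotImplemented
        return self.taxa == other.taxa and np.array_equal(self.data, other.data)


def read_fasta(path: str | Path) -> MSA:
    """Read an aligned FASTA file (case-insensitive, '-' gaps)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"no sequences in {path}")
    return MSA.from_sequences([r.id for r in records], [str(r.seq) for r in records])


def write_fasta(msa: MSA, path: str | Path, width: int = 80) -> None:
    records = [
        SeqRecord(Seq("".join(row)), id=taxon, description="")
        for taxon, row in zip(msa.taxa, msa.data)
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=width)
        writer.write_file(records)


def count_patterns(msa: MSA) -> int:
    """Number of distinct alignment columns.

    Gap and ambiguity characters are ordinary symbols here: a column
    differing only by a gap is a distinct site pattern.
    """
    cols = np.ascontiguousarray(msa.data.T)  # (n_sites, n_taxa)
    # view each column as one fixed-width string for fast uniqueness
    joined = cols.view(f"<U{msa.n_taxa}").ravel()
    return len(np.unique(joined))


def gap_fraction(msa: MSA) -> float:
    """Fraction of alignment cells that are gap characters."""
    return float(np.mean(msa.data == GAP))


def superimpose_gaps(msa: MSA, template_mask: np.ndarray) -> MSA:
    """Overwrite cells with gaps wherever `template_mask` is true.

    The mask must have the alignment's shape (rows in the MSA's taxon
    order).  Used to transplant an empirical gap structure onto a
    simulated gapless alignment.
    """
    mask = np.asarray(template_mask, dtype=bool)
    if mask.shape != msa.data.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match alignment shape {msa.data.shape}"
        )
    data = msa.data.copy()
    data[mask] = GAP
    return MSA(list(msa.taxa), data)


def gap_mask(msa: MSA) -> np.ndarray:
    """Boolean matrix marking gap cells."""
    return msa.data == GAP
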