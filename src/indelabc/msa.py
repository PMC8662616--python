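"""Multiple sequence alignments and FASTA I/O."""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

GAP = "-"


@dataclass
class Msa:
    """A rectangular multiple sequence alignment.

    Rows are (label, aligned sequence) pairs; ``-`` is the only gap
    character. Residue case is preserved as given.
    """

    labels: list[str]
    sequences: list[str]
    _gap_matrix: np.ndarray | None = field(default=None, repr=False, compare=False)

    def __post_init__(self) -> None:
        if len(self.labels) != len(self.sequences):
            raise ValueError("labels and sequences differ in number")
        if not self.sequences:
            raise ValueError("empty alignment")
        ncols = len(self.sequences[0])
        for lab, seq in zip(self.labels, self.sequences):
            if len(seq) != ncols:
                lengths = {l: len(s) for l, s in zip(self.labels, self.sequences)}
                raise ValueError(
                    f"ragged alignment: row {lab!r} has length {len(seq)}, "
                    f"expected {ncols} (row lengths: {lengths})"
                )
        if len(set(self.labels)) != len(self.labels):
            raise ValueError("duplicate sequence labels")

    @property
    def nrows(self) -> int:
        return len(self.sequences)

    @property
    def ncols(self) -> int:
        return len(self.sequences[0])

    def gap_matrix(self) -> np.ndarray:
        """Boolean (nrows, ncols) matrix, True where the cell is a gap."""
        if self._gap_matrix is None:
            arr = np.frombuffer(
                "".join(self.sequences).encode("ascii"), dtype=np.uint8
            ).reshape(self.nrows, self.ncols)
            self._gap_matrix = arr == ord(GAP)
        return self._gap_matrix

    def ungapped_lengths(self) -> np.ndarray:
        """Residue count per row (alignment length minus gaps)."""
        return self.ncols - self.gap_matrix().sum(axis=1)

    def degapped(self) -> list[tuple[str, str]]:
        """(label, sequence) pairs with all gap characters removed."""
        return [
            (lab, seq.replace(GAP, "")) for lab, seq in zip(self.labels, self.sequences)
        ]

    def rows(self) -> Iterable[tuple[str, str]]:
        return zip(self.labels, self.sequences)


def read_msa(path: str | Path, *, dot_is_gap: bool = True) -> Msa:
    """Read an aligned FASTA file.

    Parameters
    ----------
    path : file path
    dot_is_gap : translate ``.`` to ``-`` on read (default True).
    """
    path = Path(path)
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise ValueError(f"{path}: no sequences found")
    labels = [r.id for r in records]
    seqs = [str(r.seq) for r in records]
    if dot_is_gap:
        seqs = [s.replace(".", GAP) for s in seqs]
    return Msa(labels, seqs)


def write_msa(msa: Msa, path: str | Path, *, width: int = 70) -> None:
    """Write an Msa as FASTA."""
    records = [
        SeqRecord(Seq(seq), id=lab, description="") for lab, seq in msa.rows()
    ]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def write_fasta(rows: Sequence[tuple[str, str]], path: str | Path) -> None:
    """Write unaligned (label, sequence) pairs as FASTA."""
    records = [SeqRecord(Seq(seq), id=lab, description="") for lab, seq in rows]
    with open(path, "w") as fh:
        SeqIO.write(records, fh, "fasta")


def rl_prior_range(msa: Msa) -> tuple[int, int]:
    """Root-length prior bounds derived from the input sequences.

    With ls and ll the shortest and longest ungapped sequence lengths,
    the root length is taken a priori uniform on the integer interval
    [floor(0.8*ls), ceil(1.1*ll)] — floored/ceiled so the real-valued
    bounds are never excluded.
    """
    lengths = msa.ungapped_lengths()
    ls, ll = int(lengths.min()), int(lengths.max())
    # exact integer arithmetic: floor(4*ls/5), ceil(11*ll/10)
    lo = max(1, (4 * ls) // 5)
    hi = -((-11 * ll) // 10)
    return lo, hi
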