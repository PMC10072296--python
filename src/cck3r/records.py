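"""Protein sequence records and FASTA input/output.

Sequences are plain one-letter amino-acid strings over the 20 standard
residues plus ``X`` for unknown.  Terminal stop characters (``*``) are
stripped on input; any other character is rejected with the offending
record id and 1-based position.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

#: The 20 standard one-letter residues plus 'X' for unknown.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
ALLOWED_RESIDUES = frozenset(AMINO_ACIDS + "X")


class InvalidResidueError(ValueError):
    """A sequence contains a character outside the allowed alphabet."""

    def __init__(self, record_id: str, position: int, char: str):
        self.record_id = record_id
        self.position = position  # 1-based
        self.char = char
        super().__init__(
            f"record {record_id!r}: illegal residue {char!r} at position {position}"
        )


@dataclass(frozen=True)
class ProteinRecord:
    """A named protein sequence.

    Parameters
    ----------
    id : str
        Short unique identifier (FASTA header up to the first whitespace).
    residues : str
        Upper-case one-letter sequence; must be nonempty and drawn from
        the 21-letter alphabet (20 standard residues + ``X``).
    description : str
        Free-text remainder of the FASTA header.
    """

    id: str
    residues: str
    description: str = ""

    def __post_init__(self):
        if not self.id:
            raise ValueError("record id must be nonempty")
        if not self.residues:
            raise ValueError(f"record {self.id!r}: empty sequence")
        for i, ch in enumerate(self.residues):
            if ch not in ALLOWED_RESIDUES:
                raise InvalidResidueError(self.id, i + 1, ch)

    def __len__(self) -> int:
        return len(self.residues)


def _clean_sequence(raw: str) -> str:
    seq = raw.upper()
    # tolerate a single terminal stop marker from CDS translations
    while seq.endswith("*"):
        seq = seq[:-1]
    return seq


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a FASTA file into a list of :class:`ProteinRecord`.

    Order is preserved, sequences are upper-cased and terminal ``*``
    stops stripped.  Raises :class:`FileNotFoundError` for a missing
    file, :class:`ValueError` for an empty file or duplicate ids, and
    :class:`InvalidResidueError` for an illegal character.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    records = []
    seen: set[str] = set()
    for entry in SeqIO.parse(str(path), "fasta"):
        seq = _clean_sequence(str(entry.seq))
        rec = ProteinRecord(id=entry.id, residues=seq, description=entry.description)
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r} in {path}")
        seen.add(rec.id)
        records.append(rec)
    if not records:
        raise ValueError(f"no FASTA records found in {path}")
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path, width: int = 60) -> None:
    """Write records to FASTA with fixed line width (deterministic output)."""
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            header = rec.id if not rec.description or rec.description == rec.id else rec.description
            fh.write(f">{header}\n")
            for i in range(0, len(rec.residues), width):
                fh.write(rec.residues[i : i + width] + "\n")


def check_unique_ids(records: Sequence[ProteinRecord]) -> None:
    seen: set[str] = set()
    for rec in records:
        if rec.id in seen:
            raise ValueError(f"duplicate record id {rec.id!r}")
        seen.add(rec.id)
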