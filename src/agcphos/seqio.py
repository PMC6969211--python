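"""Sequence and alignment containers for kinase-domain analysis.

Sequences are plain uppercase one-letter amino-acid strings (the 20 standard
residues plus ``X`` for unknowns); alignments are gapped with ``-``.  FASTA
parsing is delegated to Biopython.
"""

from __future__ import annotations

import io
import warnings
from dataclasses import dataclass, field

from Bio import SeqIO

AA20 = set("ACDEFGHIKLMNPQRSTVWY")
ALPHABET = AA20 | {"X"}
GAP = "-"


@dataclass(frozen=True)
class KinaseSeq:
    """One kinase-domain sequence.

    Parameters
    ----------
    id : str
        Record identifier (unique within a dataset).
    residues : str
        Ungapped, uppercase one-letter amino acids; may contain ``X``.
    family : str | None
        Optional subfamily label (e.g. ``RSK``, ``PKC``).
    """

    id: str
    residues: str
    family: str | None = None

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.id}: empty sequence")
        bad = set(self.residues) - ALPHABET
        if bad:
            raise ValueError(
                f"{self.id}: invalid residue characters {sorted(bad)!r}"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass
class Alignment:
    """A multiple sequence alignment: ordered rows of equal gapped length."""

    rows: list[tuple[str, str]] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.rows:
            n = len(self.rows[0][1])
            for rid, row in self.rows:
                if len(row) != n:
                    raise ValueError(
                        f"alignment row {rid!r} has length {len(row)}, expected {n}"
                    )
        ids = [rid for rid, _ in self.rows]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise ValueError(f"duplicate id in alignment: {dup!r}")

    @property
    def length(self) -> int:
        """Number of columns."""
        return len(self.rows[0][1]) if self.rows else 0

    @property
    def ids(self) -> list[str]:
        return [rid for rid, _ in self.rows]

    def row(self, rid: str) -> str:
        for r, s in self.rows:
            if r == rid:
                return s
        raise KeyError(f"id {rid!r} not in alignment")

    def degapped(self, rid: str) -> str:
        return self.row(rid).replace(GAP, "")

    def column_of(self, rid: str, ungapped_pos: int) -> int:
        """Alignment column holding the reference row's *ungapped_pos*-th residue."""
        row = self.row(rid)
        seen = -1
        for col, ch in enumerate(row):
            if ch != GAP:
                seen += 1
                if seen == ungapped_pos:
                    return col
        raise IndexError(
            f"{rid!r}: ungapped position {ungapped_pos} beyond sequence "
            f"length {seen + 1}"
        )

    def ungapped_pos(self, rid: str, column: int) -> int | None:
        """Ungapped position of *column* in row *rid*, or None if gapped there."""
        row = self.row(rid)
        if row[column] == GAP:
            return None
        return sum(1 for ch in row[:column] if ch != GAP)


def read_sequences(source: str | io.TextIOBase) -> list[KinaseSeq]:
    """Read ungapped kinase sequences from FASTA text or a file path.

    Gap characters are stripped with a warning (the file was probably an
    alignment); duplicate ids and empty files are errors.
    """
    handle = _as_handle(source)
    seqs: list[KinaseSeq] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(handle, "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate sequence id: {rec.id!r}")
        seen.add(rec.id)
        residues = str(rec.seq).upper()
        if GAP in residues or "." in residues:
            warnings.warn(
                f"{rec.id}: gap characters stripped from FASTA record",
                stacklevel=2,
            )
            residues = residues.replace(GAP, "").replace(".", "")
        seqs.append(KinaseSeq(id=rec.id, residues=residues))
    if not seqs:
        raise ValueError("no FASTA records found")
    return seqs


def read_alignment(source: str | io.TextIOBase) -> Alignment:
    """Read an aligned FASTA (gaps ``-``) into an :class:`Alignment`."""
    handle = _as_handle(source)
    rows = [
        (rec.id, str(rec.seq).upper()) for rec in SeqIO.parse(handle, "fasta")
    ]
    if not rows:
        raise ValueError("no FASTA records found")
    return Alignment(rows=rows)


def write_fasta(seqs: list[KinaseSeq], path: str) -> None:
    with open(path, "w") as fh:
        for s in seqs:
            fh.write(f">{s.id}\n{s.residues}\n")


def write_alignment(msa: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for rid, row in msa.rows:
            fh.write(f">{rid}\n{row}\n")


def _as_handle(source: str | io.TextIOBase):
    if isinstance(source, io.TextIOBase):
        return source
    if "\n" in source or source.lstrip().startswith(">"):
        return io.StringIO(source)
    return open(source)
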