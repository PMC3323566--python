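"""Sequence and alignment I/O.

Reads/writes protein FASTA, aligned FASTA and Clustal files, validates the
amino-acid alphabet, and maintains the mapping between alignment columns and
per-sequence (ungapped) residue coordinates.

Coordinate conventions: everything internal is 0-based half-open; every
user-facing report (TSV/BED name fields, motif hits, CLI output) is 1-based
inclusive, matching the residue numbering conventions of the protein
literature.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
from Bio import AlignIO, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord as _BioSeqRecord

#: Canonical 20-letter amino-acid alphabet, alphabetical order.
AA20: str = "ACDEFGHIKLMNPQRSTVWY"
AA_SET = frozenset(AA20)
AA_INDEX = {aa: i for i, aa in enumerate(AA20)}

GAP = "-"
#: Gap characters accepted on input; all normalized to '-'.
GAP_CHARS = frozenset("-.")
#: Unknown-residue marker. Ambiguity codes are folded into it when permissive.
UNKNOWN = "X"
_AMBIGUOUS = frozenset("BZJUO*")

ALIGNMENT_DIALECTS = ("aligned-fasta", "clustal")


class ParseError(ValueError):
    """Raised for malformed sequence/alignment input."""


@dataclass(frozen=True)
class SequenceRecord:
    """An ungapped, upper-case protein sequence with its identifier."""

    id: str
    residues: str

    def __post_init__(self) -> None:
        if not self.id:
            raise ParseError("sequence record has an empty id")
        object.__setattr__(self, "residues", self.residues.upper())
        bad = set(self.residues) - AA_SET - {UNKNOWN}
        if bad & GAP_CHARS:
            raise ParseError(
                f"record {self.id!r}: residues must be ungapped "
                f"(found {sorted(bad & GAP_CHARS)})"
            )
        if bad:
            raise ParseError(
                f"record {self.id!r}: unknown letters {sorted(bad)}; "
                f"use permissive=True to fold them into '{UNKNOWN}'"
            )

    def __len__(self) -> int:
        return len(self.residues)


@dataclass(frozen=True)
class Alignment:
    """Equal-length gapped protein sequences with unique identifiers.

    ``rows`` hold upper-case residues plus ``'-'`` gaps; at least two rows
    are required for any column statistic to be meaningful.
    """

    ids: tuple[str, ...]
    rows: tuple[str, ...]
    gap_char: str = GAP

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.rows):
            raise ParseError("ids and rows differ in count")
        if len(self.ids) < 2:
            raise ParseError("an alignment needs at least 2 sequences")
        if len(set(self.ids)) != len(self.ids):
            dupes = sorted({i for i in self.ids if self.ids.count(i) > 1})
            raise ParseError(f"duplicate sequence ids: {dupes}")
        lengths = {len(r) for r in self.rows}
        if len(lengths) != 1:
            detail = ", ".join(
                f"{i}={len(r)}" for i, r in zip(self.ids, self.rows)
            )
            raise ParseError(f"ragged alignment rows ({detail})")
        if self.length < 1:
            raise ParseError("alignment has zero columns")
        for i, row in zip(self.ids, self.rows):
            bad = set(row) - AA_SET - {UNKNOWN, self.gap_char}
            if bad:
                raise ParseError(f"row {i!r}: unexpected letters {sorted(bad)}")

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    @property
    def length(self) -> int:
        return len(self.rows[0])

    def column(self, col: int) -> str:
        """Residues (and gaps) of column ``col`` (0-based), top to bottom."""
        if not 0 <= col < self.length:
            raise IndexError(f"column {col} outside [0, {self.length})")
        return "".join(row[col] for row in self.rows)

    def ungapped(self, row: int) -> SequenceRecord:
        """Row ``row`` with gaps stripped, as a :class:`SequenceRecord`."""
        return SequenceRecord(self.ids[row], self.rows[row].replace(self.gap_char, ""))

    def char_matrix(self) -> np.ndarray:
        """(n_rows, length) array of single characters."""
        return np.frombuffer(
            "".join(self.rows).encode("ascii"), dtype="S1"
        ).reshape(self.n_rows, self.length).astype("U1")


@dataclass(frozen=True)
class ColumnMap:
    """Bidirectional map between alignment columns and residue positions.

    ``residue_index[i, c]`` is the 0-based position of column ``c`` within the
    ungapped sequence of row ``i``, or -1 at a gap. ``column_of[i][p]`` is the
    alignment column holding residue ``p`` of row ``i``.
    """

    residue_index: np.ndarray
    column_of: tuple[np.ndarray, ...]

    def residue_to_column(self, row: int, pos: int) -> int:
        return int(self.column_of[row][pos])

    def column_to_residue(self, row: int, col: int) -> int | None:
        idx = int(self.residue_index[row, col])
        return None if idx < 0 else idx


# ---------------------------------------------------------------------------
# normalization helpers

def _normalize(raw: str, *, permissive: bool, where: str) -> str:
    out = []
    for ch in raw.upper():
        if ch in GAP_CHARS:
            out.append(GAP)
        elif ch in AA_SET or ch == UNKNOWN:
            out.append(ch)
        elif permissive and ch in _AMBIGUOUS:
            out.append(UNKNOWN)
        else:
            raise ParseError(f"{where}: unknown letter {ch!r}")
    return "".join(out)


def _header_line_numbers(path: Path) -> dict[int, int]:
    """Map record ordinal -> 1-based line number of its FASTA header."""
    lines: dict[int, int] = {}
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            if line.startswith(">"):
                lines[n] = lineno
                n += 1
    return lines


# ---------------------------------------------------------------------------
# operations

def read_fasta(path: str | Path, *, permissive: bool = False) -> list[SequenceRecord]:
    """Read an (ungapped) protein FASTA file.

    Residues are upper-cased and validated against the 20-letter alphabet
    (plus ``X``); with ``permissive=True`` ambiguity codes B/Z/J/U/O/* are
    folded into ``X``. Duplicate ids, empty sequences and empty headers raise
    :class:`ParseError` naming the offending line.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    headers = _header_line_numbers(path)
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for n, rec in enumerate(SeqIO.parse(str(path), "fasta")):
        line = headers.get(n, 0)
        if not rec.id:
            raise ParseError(f"{path}:{line}: empty FASTA header")
        if not str(rec.seq):
            raise ParseError(f"{path}:{line}: record {rec.id!r} has an empty sequence")
        if rec.id in seen:
            raise ParseError(f"{path}:{line}: duplicate id {rec.id!r}")
        seen.add(rec.id)
        residues = _normalize(str(rec.seq), permissive=permissive, where=f"{path}:{rec.id}")
        if GAP in residues:
            raise ParseError(f"{path}:{line}: record {rec.id!r} contains gap characters")
        records.append(SequenceRecord(rec.id, residues))
    if not records:
        raise ParseError(f"{path}: no FASTA records found")
    return records


def write_fasta(records: Iterable[SequenceRecord], path: str | Path) -> None:
    """Write records as 60-column wrapped FASTA."""
    bio = [_BioSeqRecord(Seq(r.residues), id=r.id, description="") for r in records]
    SeqIO.write(bio, str(path), "fasta")


def read_alignment(
    path: str | Path, dialect: str = "aligned-fasta", *, permissive: bool = False
) -> Alignment:
    """Read a multiple alignment in aligned-FASTA or Clustal format.

    ``'.'`` gaps are normalized to ``'-'`` and case is canonicalized. The
    Clustal reader tolerates version headers and ignores conservation lines.
    Ragged rows raise :class:`ParseError` listing the offending id and
    lengths.
    """
    path = Path(path)
    if dialect not in ALIGNMENT_DIALECTS:
        raise ValueError(f"dialect must be one of {ALIGNMENT_DIALECTS}, got {dialect!r}")
    if not path.exists():
        raise FileNotFoundError(path)

    ids: list[str] = []
    rows: list[str] = []
    if dialect == "aligned-fasta":
        headers = _header_line_numbers(path)
        for n, rec in enumerate(SeqIO.parse(str(path), "fasta")):
            line = headers.get(n, 0)
            if not str(rec.seq):
                raise ParseError(f"{path}:{line}: record {rec.id!r} has an empty row")
            ids.append(rec.id)
            rows.append(_normalize(str(rec.seq), permissive=permissive, where=f"{path}:{rec.id}"))
        if not ids:
            raise ParseError(f"{path}: no FASTA records found")
    else:
        try:
            aln = AlignIO.read(str(path), "clustal")
        except ValueError as exc:
            raise ParseError(f"{path}: not a valid Clustal file ({exc})") from exc
        for rec in aln:
            ids.append(rec.id)
            rows.append(_normalize(str(rec.seq), permissive=permissive, where=f"{path}:{rec.id}"))

    lengths = {len(r) for r in rows}
    if len(lengths) != 1:
        detail = ", ".join(f"{i}={len(r)}" for i, r in zip(ids, rows))
        raise ParseError(f"{path}: ragged alignment rows ({detail})")
    return Alignment(tuple(ids), tuple(rows))


def write_alignment(aln: Alignment, path: str | Path, dialect: str = "aligned-fasta") -> None:
    """Write an alignment as aligned FASTA (60-col wrap) or Clustal."""
    if dialect not in ALIGNMENT_DIALECTS:
        raise ValueError(f"dialect must be one of {ALIGNMENT_DIALECTS}, got {dialect!r}")
    bio = [_BioSeqRecord(Seq(r), id=i, description="") for i, r in zip(aln.ids, aln.rows)]
    if dialect == "aligned-fasta":
        SeqIO.write(bio, str(path), "fasta")
    else:
        from Bio.Align import MultipleSeqAlignment

        AlignIO.write(MultipleSeqAlignment(bio), str(path), "clustal")


def build_column_map(aln: Alignment) -> ColumnMap:
    """Column <-> residue coordinate map for every row of the alignment.

    For each row, residue positions are strictly increasing across non-gap
    columns and the number of mapped positions equals the ungapped length.
    """
    mat = aln.char_matrix()
    nongap = mat != aln.gap_char
    # cumulative count of residues up to and including each column, minus 1
    residue_index = np.cumsum(nongap, axis=1) - 1
    residue_index[~nongap] = -1
    column_of = tuple(np.flatnonzero(nongap[i]) for i in range(aln.n_rows))
    return ColumnMap(residue_index=residue_index, column_of=column_of)
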