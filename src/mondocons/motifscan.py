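"""Protein motif pattern engine and family-wide scanning.

Two pattern dialects are supported:

* ``elm`` — ordinary regular-expression syntax as used by the Eukaryotic
  Linear Motif resource, where ``{m,n}`` braces are quantifiers
  (e.g. the MAPK kinase-docking motif ``[KR]{0,2}[KR].{0,2}[KR].{2,4}[ILVM].[ILVF]``).
* ``braces-exclusion`` — a fixed-length per-position dialect where ``[...]``
  lists permitted residues, ``{...}`` lists prohibited residues, a bare
  letter is a literal and ``x``/``.`` match any of the 20 residues
  (the nine-amino-acid transactivation-domain signature uses this form).

Scanning operates on ungapped sequences; hits found through an alignment are
back-mapped to alignment-column intervals so motif occurrence can be compared
across a family.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .seqio import AA20, AA_SET, Alignment, ColumnMap, SequenceRecord, build_column_map

DIALECTS = ("elm", "braces-exclusion")


class MotifCompileError(ValueError):
    """Pattern failed to compile; the message names the offending position."""


@dataclass(frozen=True)
class Motif:
    """A named, compiled motif pattern.

    ``classes`` is populated for the braces-exclusion dialect only: one
    frozenset of permitted residues per position (the pattern is
    fixed-length by construction).
    """

    name: str
    dialect: str
    pattern: str
    regex: re.Pattern = field(repr=False, compare=False)
    length_range: tuple[int, int | None] = (0, None)
    classes: tuple[frozenset, ...] | None = None

    @property
    def fixed_length(self) -> int | None:
        lo, hi = self.length_range
        return lo if hi == lo else None


@dataclass(frozen=True)
class MotifHit:
    """A located match. ``start``/``end`` are 1-based inclusive residue
    coordinates within the ungapped sequence; ``col_start``/``col_end`` are
    1-based inclusive alignment columns when scanned through an alignment."""

    motif: str
    seq_id: str
    start: int
    end: int
    matched: str
    col_start: int | None = None
    col_end: int | None = None


# ---------------------------------------------------------------------------
# compilation

def _parse_braces_exclusion(pattern: str) -> list[frozenset]:
    classes: list[frozenset] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch in "[{":
            close = "]" if ch == "[" else "}"
            j = pattern.find(close, i + 1)
            if j < 0:
                raise MotifCompileError(f"position {i + 1}: unbalanced {ch!r}")
            members = pattern[i + 1 : j].upper()
            if not members:
                raise MotifCompileError(f"position {i + 1}: empty class")
            bad = set(members) - AA_SET
            if bad:
                raise MotifCompileError(
                    f"position {i + 1}: non-residue letters {sorted(bad)} in class"
                )
            allowed = frozenset(members) if ch == "[" else AA_SET - frozenset(members)
            if not allowed:
                raise MotifCompileError(f"position {i + 1}: class prohibits every residue")
            classes.append(allowed)
            i = j + 1
        elif ch in "]}":
            raise MotifCompileError(f"position {i + 1}: unbalanced {ch!r}")
        elif ch in "xX.":
            classes.append(frozenset(AA_SET))
            i += 1
        elif ch.upper() in AA_SET:
            classes.append(frozenset(ch.upper()))
            i += 1
        else:
            raise MotifCompileError(
                f"position {i + 1}: unexpected token {ch!r} for braces-exclusion dialect"
            )
    if not classes:
        raise MotifCompileError("empty pattern")
    return classes


def _elm_length_range(pattern: str) -> tuple[int, int | None]:
    """Length bounds for the elm subset (classes, literals, '.', {m[,n]})."""
    lo = hi = 0
    i = 0
    try:
        while i < len(pattern):
            ch = pattern[i]
            if ch == "[":
                i = pattern.index("]", i) + 1
            elif ch == ".":
                i += 1
            elif ch.upper() in AA_SET:
                i += 1
            else:
                return 0, None  # construct outside the subset: bounds unknown
            step_lo = step_hi = 1
            if i < len(pattern) and pattern[i] == "{":
                j = pattern.index("}", i)
                body = pattern[i + 1 : j]
                if "," in body:
                    a, b = body.split(",", 1)
                    step_lo, step_hi = int(a), int(b)
                else:
                    step_lo = step_hi = int(body)
                i = j + 1
            lo += step_lo
            hi += step_hi
    except (ValueError, IndexError):
        return 0, None
    return lo, hi


def compile_motif(pattern: str, dialect: str, name: str = "") -> Motif:
    """Compile a raw pattern string under the given dialect."""
    if dialect not in DIALECTS:
        raise MotifCompileError(f"unknown dialect {dialect!r}; expected one of {DIALECTS}")
    if not pattern:
        raise MotifCompileError("empty pattern")
    name = name or pattern
    if dialect == "braces-exclusion":
        classes = _parse_braces_exclusion(pattern)
        rx = "".join(
            "[" + "".join(sorted(cls)) + "]" if len(cls) > 1 else next(iter(cls))
            for cls in classes
        )
        n = len(classes)
        return Motif(
            name=name,
            dialect=dialect,
            pattern=pattern,
            regex=re.compile(rx),
            length_range=(n, n),
            classes=tuple(classes),
        )
    try:
        regex = re.compile(pattern)
    except re.error as exc:
        pos = f" at position {exc.pos + 1}" if exc.pos is not None else ""
        raise MotifCompileError(f"invalid elm pattern{pos}: {exc.msg}") from exc
    return Motif(
        name=name,
        dialect=dialect,
        pattern=pattern,
        regex=regex,
        length_range=_elm_length_range(pattern),
    )


# ---------------------------------------------------------------------------
# built-in library

@dataclass
class MotifLibrary:
    """A named collection of motifs with unique names."""

    motifs: dict[str, Motif] = field(default_factory=dict)

    def add(self, motif: Motif) -> None:
        if motif.name in self.motifs:
            raise ValueError(f"duplicate motif name {motif.name!r}")
        self.motifs[motif.name] = motif

    def __getitem__(self, name: str) -> Motif:
        return self.motifs[name]

    def __contains__(self, name: str) -> bool:
        return name in self.motifs

    def __iter__(self):
        return iter(self.motifs.values())

    def __len__(self) -> int:
        return len(self.motifs)

    @classmethod
    def from_file(cls, path: str | Path) -> "MotifLibrary":
        """Read 'name <tab> dialect <tab> pattern' lines ('#' comments)."""
        lib = cls()
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].rstrip()
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 3:
                raise MotifCompileError(
                    f"{path}:{lineno}: expected 'name<TAB>dialect<TAB>pattern'"
                )
            name, dialect, pattern = parts
            lib.add(compile_motif(pattern, dialect, name=name))
        return lib

    def to_file(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for m in self:
                fh.write(f"{m.name}\t{m.dialect}\t{m.pattern}\n")


#: (name, dialect, pattern) for every motif signature carried by the package.
#: Signatures printed with typographic emphasis/spacing are canonicalized to
#: contiguous patterns with 'x' as the wildcard.
BUILTIN_PATTERNS: tuple[tuple[str, str, str], ...] = (
    # nine-amino-acid transactivation domain recognized by CBP/p300-family
    # coactivators; braces prohibit, brackets permit
    ("9aaTAD", "braces-exclusion",
     "[GSTDENQWYM]{KRHCGP}[FLIVMW]{KRHCGP}{CGP}{KRHCGP}[FLIVMW][FLIVAMW]{KRHCP}"),
    # MAPK kinase-docking motif (basic cluster + hydrophobic Φ-x-Φ)
    ("MAPK_docking", "elm", "[KR]{0,2}[KR].{0,2}[KR].{2,4}[ILVM].[ILVF]"),
    # nuclear receptor box (coactivator LxxLL) and its conserved Mondo variant
    ("NRB_LxxLL", "braces-exclusion", "LxxLL"),
    ("NRB_LxQLLT", "braces-exclusion", "LxQLLT"),
    # glucose-6-phosphate recognition motifs (phosphate-contacting Ser/Thr)
    ("G6P_SxSTxxST", "braces-exclusion", "Sx[ST]xx[ST]"),
    ("GPI_SxSTxxT", "braces-exclusion", "Sx[ST]xxT"),
    # 12-residue MCR6 signature centred on the [ST]DTLF[ST] core
    ("MCR6_signature", "braces-exclusion", "[MLD][SNED][EDML][FIM][ST]DTLF[ST][STM][LTI]"),
    # conserved extension directly downstream of MCRIII
    ("MCRIII_ext", "braces-exclusion", "[KR]x[KRN][NSTP][PLIV][VFI][CIV]xF[AVI][STV]P[LIV]"),
    # cytoplasmic retention signal in the latter half of MCRIV
    ("CRS_MCRIV", "braces-exclusion", "VxxEY[KH]KWRx[FY][FY][KR]"),
    # near-invariant MCRI core
    ("MCRI_core", "braces-exclusion", "HSGxFMxS"),
)


def builtin_library() -> MotifLibrary:
    """The package's built-in motif signatures, all compiled."""
    lib = MotifLibrary()
    for name, dialect, pattern in BUILTIN_PATTERNS:
        lib.add(compile_motif(pattern, dialect, name=name))
    return lib


# ---------------------------------------------------------------------------
# scanning

def scan_sequence(
    seq: SequenceRecord, motif: Motif, overlapping: bool = True
) -> list[MotifHit]:
    """All matches of ``motif`` in an ungapped sequence, sorted by start.

    With ``overlapping=True`` a match is attempted at every position
    (lookahead scan; variable-length elm patterns report the leftmost-longest
    match at each start). With ``overlapping=False`` the scan resumes after
    each match's end.
    """
    s = seq.residues
    hits: list[MotifHit] = []
    if overlapping:
        lo, hi = motif.length_range
        variable = hi is not None and hi != lo
        for i in range(len(s)):
            if variable:
                # leftmost-longest: try anchored lengths from longest down
                for span in range(min(hi, len(s) - i), max(lo, 1) - 1, -1):
                    if motif.regex.fullmatch(s, i, i + span):
                        hits.append(
                            MotifHit(motif.name, seq.id, i + 1, i + span, s[i : i + span])
                        )
                        break
            else:
                m = motif.regex.match(s, i)
                if m and m.end() > m.start():
                    hits.append(
                        MotifHit(motif.name, seq.id, m.start() + 1, m.end(), m.group(0))
                    )
    else:
        for m in motif.regex.finditer(s):
            if m.end() > m.start():
                hits.append(
                    MotifHit(motif.name, seq.id, m.start() + 1, m.end(), m.group(0))
                )
    return hits


def scan_alignment(
    aln: Alignment,
    motif: Motif,
    overlapping: bool = True,
    column_map: ColumnMap | None = None,
) -> list[MotifHit]:
    """Scan each row ungapped and back-map hits to alignment columns.

    A hit spanning a gap in its own row reports the column interval from the
    column of its first residue to the column of its last (inclusive,
    1-based).
    """
    cmap = column_map or build_column_map(aln)
    hits: list[MotifHit] = []
    for row in range(aln.n_rows):
        record = aln.ungapped(row)
        if not record.residues:
            continue
        for hit in scan_sequence(record, motif, overlapping=overlapping):
            col_start = cmap.residue_to_column(row, hit.start - 1) + 1
            col_end = cmap.residue_to_column(row, hit.end - 1) + 1
            hits.append(replace(hit, col_start=col_start, col_end=col_end))
    return hits


def motif_column_consensus(
    hits: Sequence[MotifHit], aln: Alignment, window: int = 0
) -> np.ndarray:
    """Per-column fraction of sequences carrying a hit at (or near) the column.

    A sequence counts for column ``c`` when one of its hits' column intervals
    intersects ``[c - window, c + window]``. Values are in [0, 1]; a
    family-wide motif produces a plateau of height ≈ carrier fraction, while
    sporadic matches stay near zero.
    """
    covered = np.zeros((aln.n_rows, aln.length), dtype=bool)
    row_of = {sid: i for i, sid in enumerate(aln.ids)}
    for hit in hits:
        if hit.col_start is None or hit.col_end is None:
            raise ValueError("consensus needs alignment-scanned hits (column intervals)")
        row = row_of[hit.seq_id]
        lo = max(0, hit.col_start - 1 - window)
        hi = min(aln.length, hit.col_end + window)
        covered[row, lo:hi] = True
    return covered.any(axis=0) * covered.sum(axis=0) / aln.n_rows


# ---------------------------------------------------------------------------
# output

def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "motif": h.motif,
                "seq_id": h.seq_id,
                "start": h.start,
                "end": h.end,
                "matched": h.matched,
                "col_start": h.col_start,
                "col_end": h.col_end,
            }
            for h in hits
        ],
        columns=["motif", "seq_id", "start", "end", "matched", "col_start", "col_end"],
    )


def write_hits_tsv(hits: Sequence[MotifHit], path: str | Path) -> None:
    hits_to_frame(hits).to_csv(path, sep="\t", index=False)


def write_hits_bed(hits: Sequence[MotifHit], path: str | Path, chrom: str = "alignment") -> None:
    """Column-space BED (0-based half-open); requires alignment-scanned hits."""
    with open(path, "w") as fh:
        for h in hits:
            if h.col_start is None or h.col_end is None:
                raise ValueError("BED output needs alignment-scanned hits")
            fh.write(f"{chrom}\t{h.col_start - 1}\t{h.col_end}\t{h.motif}:{h.seq_id}\n")
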