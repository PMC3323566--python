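"""Helical-wheel projection and compositional-bias annotation.

The helical wheel projects a candidate α-helical segment at the ideal 100°
per residue (3.6 residues per turn), so residues on the same helix face sit
within ~50° of one another on the wheel. Conservation can be layered on via
per-column "chemical identity" flags: a column is flagged when a single
physicochemical group accounts for at least 75% (default) of its occupancy.

The compositional-bias scanner finds proline-rich / glutamine-rich style
low-complexity regions with a transparent sliding-window composition rule,
and classifies a user-supplied central region as proline, glutamine or
neither.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .conservation import Grouping, count_matrix, default_grouping
from .seqio import Alignment, SequenceRecord

DEGREES_PER_RESIDUE = 100.0  # ideal alpha helix, 3.6 residues/turn


@dataclass(frozen=True)
class WheelPosition:
    index: int          # 1-based within the segment
    residue: str
    angle: float        # degrees in [0, 360)
    turn: int           # 0-based helical turn number
    flags: tuple[str, ...] = ()


@dataclass(frozen=True)
class HelicalWheelLayout:
    seq_id: str
    start: int          # 1-based inclusive residue coordinates of the segment
    end: int
    positions: tuple[WheelPosition, ...]

    def to_json(self) -> str:
        return json.dumps(
            {
                "seq_id": self.seq_id,
                "start": self.start,
                "end": self.end,
                "positions": [
                    {
                        "index": p.index,
                        "residue": p.residue,
                        "angle": p.angle,
                        "turn": p.turn,
                        "flags": list(p.flags),
                    }
                    for p in self.positions
                ],
            },
            indent=2,
        )


@dataclass(frozen=True)
class BiasInterval:
    """A maximal residue-class-rich interval (1-based inclusive)."""

    seq_id: str
    start: int
    end: int
    residue: str
    fraction: float

    def __len__(self) -> int:
        return self.end - self.start + 1


def helical_wheel(
    seq: SequenceRecord,
    start: int,
    end: int,
    flags: dict[int, Sequence[str]] | None = None,
) -> HelicalWheelLayout:
    """Project residues ``start..end`` (1-based inclusive) onto a helical wheel.

    Position ``i`` within the segment receives angle ``((i-1) * 100) mod 360``.
    Segments longer than ~36 residues wrap the wheel many times and become
    hard to read, but are not rejected. ``flags`` maps segment positions
    (1-based) to annotation labels (e.g. ``("conserved",)``).
    """
    if not (1 <= start <= end <= len(seq)):
        raise IndexError(
            f"segment {start}..{end} outside sequence {seq.id!r} of length {len(seq)}"
        )
    flags = flags or {}
    positions = []
    for i, residue in enumerate(seq.residues[start - 1 : end], 1):
        total = (i - 1) * DEGREES_PER_RESIDUE
        positions.append(
            WheelPosition(
                index=i,
                residue=residue,
                angle=total % 360.0,
                turn=int(total // 360),
                flags=tuple(flags.get(i, ())),
            )
        )
    return HelicalWheelLayout(seq.id, start, end, tuple(positions))


def chemical_identity_flags(
    aln: Alignment, grouping: Grouping | None = None, threshold: float = 0.75
) -> np.ndarray:
    """Per-column flag: modal functional group holds ≥ threshold of occupancy.

    Invariant columns are always flagged (their modal group share is 1);
    empty columns never are. Returns a boolean array over alignment columns.
    """
    if not 0.0 < threshold <= 1.0:
        raise ValueError("threshold must be in (0, 1]")
    grouping = grouping or default_grouping()
    counts = count_matrix(aln)
    gidx = grouping.group_index()
    gcounts = np.zeros((aln.length, grouping.k))
    for g in range(grouping.k):
        gcounts[:, g] = counts[:, gidx == g].sum(axis=1)
    occ = gcounts.sum(axis=1)
    share = np.divide(
        gcounts.max(axis=1), occ, out=np.zeros(aln.length), where=occ > 0
    )
    return (occ > 0) & (share >= threshold)


def low_complexity_scan(
    seq: SequenceRecord,
    residue: str,
    window: int = 25,
    fraction: float = 0.35,
) -> list[BiasInterval]:
    """Sliding-window compositional-bias scan for one residue class.

    Every length-``window`` window whose share of ``residue`` reaches
    ``fraction`` is flagged; overlapping flagged windows merge into maximal
    intervals, which are trimmed to start and end on the target residue, and
    the reported fraction is recomputed over the merged span. Intervals are
    disjoint by construction.
    """
    if window < 5:
        raise ValueError("window must be ≥ 5")
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    residue = residue.upper()
    s = seq.residues
    n = len(s)
    if n < window:
        return []
    is_target = np.frombuffer(s.encode("ascii"), dtype="S1") == residue.encode("ascii")
    csum = np.concatenate(([0], np.cumsum(is_target)))
    win_counts = csum[window:] - csum[:-window]            # count in s[i:i+window]
    flagged = np.flatnonzero(win_counts / window >= fraction)
    if flagged.size == 0:
        return []

    intervals: list[BiasInterval] = []
    run_start = prev = int(flagged[0])
    spans: list[tuple[int, int]] = []
    for i in flagged[1:]:
        i = int(i)
        if i <= prev + window:  # windows overlap or touch: same merged span
            prev = i
        else:
            spans.append((run_start, prev + window))
            run_start = prev = i
    spans.append((run_start, prev + window))

    for lo, hi in spans:  # 0-based half-open; trim to target residues
        idx = np.flatnonzero(is_target[lo:hi])
        if idx.size == 0:
            continue
        lo2, hi2 = lo + int(idx[0]), lo + int(idx[-1]) + 1
        frac = float((csum[hi2] - csum[lo2]) / (hi2 - lo2))
        intervals.append(BiasInterval(seq.id, lo2 + 1, hi2, residue, frac))
    return intervals


def classify_central_region(
    seq: SequenceRecord,
    region: tuple[int, int],
    window: int = 25,
    fraction: float = 0.35,
    min_length: int = 25,
) -> str:
    """Classify a region (1-based inclusive) as 'proline', 'glutamine' or 'neither'.

    Proline wins when a P-rich interval of at least ``min_length`` residues
    lies within the region; otherwise glutamine is checked the same way.
    """
    start, end = region
    if not (1 <= start <= end <= len(seq)):
        raise IndexError(
            f"region {start}..{end} outside sequence {seq.id!r} of length {len(seq)}"
        )
    sub = SequenceRecord(seq.id, seq.residues[start - 1 : end])
    for residue, label in (("P", "proline"), ("Q", "glutamine")):
        for iv in low_complexity_scan(sub, residue, window=window, fraction=fraction):
            if len(iv) >= min_length:
                return label
    return "neither"


def write_bias_tsv(intervals: Sequence[BiasInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        fh.write("seq_id\tstart\tend\tresidue\tfraction\n")
        for iv in intervals:
            fh.write(f"{iv.seq_id}\t{iv.start}\t{iv.end}\t{iv.residue}\t{iv.fraction:.4f}\n")
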