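"""Seeded synthetic protein-family alignments with planted ground truth.

The generator emulates the column-level statistical structure of a deep
metazoan-style family alignment:

* blocks of strongly conserved columns (one dominant residue per column at a
  configurable dominance probability) — analogues of conserved domains;
* invariant columns (exactly one residue type across all sequences);
* group-constrained columns (residues drawn from one physicochemical class,
  so amino-acid entropy is high but functional-group entropy is 0);
* autapomorphy columns occupied by only a handful of sequences (lineage-
  specific insertions that the occupancy filter is designed to remove);
* literal motif instances planted at a fixed column block in a configurable
  fraction of sequences;
* background columns sampled i.i.d. from a background distribution, with a
  small per-cell gap rate.

Sequences are sampled independently given the column distributions (a star
phylogeny): downstream statistics are column-wise, so tree structure is
deliberately not modelled. A single integer seed drives one generator
stream, making emission byte-identical across runs. Ground truth is
self-checked against the emitted alignment on every emission.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Sequence

import numpy as np

from .conservation import BLOSUM62_BACKGROUND, DEFAULT_GROUPS_8
from .seqio import AA20, Alignment, GAP, build_column_map

_AA_ARRAY = np.array(list(AA20))


class SpecError(ValueError):
    """Conflicting or out-of-bounds planted features."""


@dataclass(frozen=True)
class ConservedBlock:
    """A run of conserved columns: per-column dominant residue at probability
    ``dominance``, other cells drawing a random non-dominant residue."""

    start: int          # 0-based column
    length: int
    dominance: float = 0.9

    @property
    def interval(self) -> tuple[int, int]:
        return (self.start, self.start + self.length)


@dataclass(frozen=True)
class MotifPlant:
    """A literal motif instance written into carrier rows at fixed columns."""

    name: str
    literal: str
    col_start: int      # 0-based column
    carrier_fraction: float = 0.9


@dataclass
class SyntheticFamilySpec:
    """Generator parameters; defaults come from :func:`default_family_spec`."""

    n_sequences: int
    n_columns: int
    seed: int
    invariant_columns: dict[int, str] = field(default_factory=dict)
    group_columns: dict[int, str] = field(default_factory=dict)  # col -> group label
    conserved_blocks: list[ConservedBlock] = field(default_factory=list)
    motif_plants: list[MotifPlant] = field(default_factory=list)
    autapomorphy_columns: dict[int, int] = field(default_factory=dict)  # col -> carriers
    background: np.ndarray = field(default_factory=lambda: BLOSUM62_BACKGROUND.copy())
    indel_rate: float = 0.03

    def validate(self) -> None:
        if self.n_sequences < 2 or self.n_columns < 1:
            raise SpecError("need ≥ 2 sequences and ≥ 1 column")
        claimed: dict[int, str] = {}

        def claim(cols: Sequence[int], owner: str, shareable_with: set[str] = set()) -> None:
            for c in cols:
                if not 0 <= c < self.n_columns:
                    raise SpecError(f"{owner} column {c} outside alignment")
                prev = claimed.get(c)
                if prev is not None and prev not in shareable_with:
                    raise SpecError(f"column {c}: {owner} conflicts with {prev}")
                claimed[c] = owner

        for block in self.conserved_blocks:
            if not 0.0 < block.dominance <= 1.0:
                raise SpecError("block dominance must be in (0,1]")
            claim(range(*block.interval), "block")
        # invariant columns may sit inside conserved blocks (domain cores)
        claim(self.invariant_columns, "invariant", shareable_with={"block"})
        for col, res in self.invariant_columns.items():
            if res not in AA20:
                raise SpecError(f"invariant column {col}: residue {res!r} not standard")
        for col, label in self.group_columns.items():
            members = DEFAULT_GROUPS_8.get(label)
            if members is None:
                raise SpecError(f"group column {col}: unknown group {label!r}")
            if len(members) < 2:
                raise SpecError(f"group column {col}: group {label!r} has one residue; "
                                "plant an invariant column instead")
        claim(self.group_columns, "group")
        for plant in self.motif_plants:
            if not 0.0 < plant.carrier_fraction <= 1.0:
                raise SpecError("carrier fraction must be in (0,1]")
            if set(plant.literal) - set(AA20):
                raise SpecError(f"motif {plant.name}: literal must be standard residues")
            claim(range(plant.col_start, plant.col_start + len(plant.literal)), "motif")
        for col, carriers in self.autapomorphy_columns.items():
            if not 1 <= carriers < self.n_sequences:
                raise SpecError(f"autapomorphy column {col}: bad carrier count {carriers}")
        claim(self.autapomorphy_columns, "autapomorphy")

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticFamilySpec":
        raw = json.loads(Path(path).read_text())
        return cls(
            n_sequences=raw["n_sequences"],
            n_columns=raw["n_columns"],
            seed=raw["seed"],
            invariant_columns={int(k): v for k, v in raw.get("invariant_columns", {}).items()},
            group_columns={int(k): v for k, v in raw.get("group_columns", {}).items()},
            conserved_blocks=[ConservedBlock(**b) for b in raw.get("conserved_blocks", [])],
            motif_plants=[MotifPlant(**m) for m in raw.get("motif_plants", [])],
            autapomorphy_columns={
                int(k): int(v) for k, v in raw.get("autapomorphy_columns", {}).items()
            },
            background=np.asarray(raw.get("background", BLOSUM62_BACKGROUND), dtype=float),
            indel_rate=raw.get("indel_rate", 0.03),
        )

    def to_json(self, path: str | Path) -> None:
        raw = {
            "n_sequences": self.n_sequences,
            "n_columns": self.n_columns,
            "seed": self.seed,
            "invariant_columns": {str(k): v for k, v in self.invariant_columns.items()},
            "group_columns": {str(k): v for k, v in self.group_columns.items()},
            "conserved_blocks": [asdict(b) for b in self.conserved_blocks],
            "motif_plants": [asdict(m) for m in self.motif_plants],
            "autapomorphy_columns": {str(k): v for k, v in self.autapomorphy_columns.items()},
            "background": list(self.background),
            "indel_rate": self.indel_rate,
        }
        Path(path).write_text(json.dumps(raw, indent=2) + "\n")


@dataclass
class GroundTruth:
    """Planted-feature annotations, in the emitted alignment's coordinates.

    Column features are 0-based; motif hits are (seq_id, start, end) with
    1-based inclusive residue coordinates plus the planted column interval.
    """

    invariant_columns: set[int]
    conserved_blocks: list[tuple[int, int]]            # 0-based half-open
    motif_hits: list[tuple[str, int, int, str]]        # (seq_id, start, end, name)
    motif_column_intervals: dict[str, tuple[int, int]]  # name -> half-open columns
    low_occupancy_columns: set[int]
    group_columns: set[int]

    def to_json(self, path: str | Path) -> None:
        raw = {
            "invariant_columns": sorted(self.invariant_columns),
            "conserved_blocks": self.conserved_blocks,
            "motif_hits": self.motif_hits,
            "motif_column_intervals": {
                k: list(v) for k, v in self.motif_column_intervals.items()
            },
            "low_occupancy_columns": sorted(self.low_occupancy_columns),
            "group_columns": sorted(self.group_columns),
        }
        Path(path).write_text(json.dumps(raw, indent=2) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GroundTruth":
        raw = json.loads(Path(path).read_text())
        return cls(
            invariant_columns=set(raw["invariant_columns"]),
            conserved_blocks=[tuple(b) for b in raw["conserved_blocks"]],
            motif_hits=[tuple(h) for h in raw["motif_hits"]],
            motif_column_intervals={
                k: tuple(v) for k, v in raw["motif_column_intervals"].items()
            },
            low_occupancy_columns=set(raw["low_occupancy_columns"]),
            group_columns=set(raw["group_columns"]),
        )


def default_family_spec(seed: int) -> SyntheticFamilySpec:
    """The canonical study conditions used throughout the test suite.

    34 sequences × 1,100 columns; five conserved blocks of 16 columns at
    0.9 dominance containing 24 invariant columns between them; one
    6-residue glucose-6-phosphate-style motif (SDTLFT) planted at 90%
    carriage; eight autapomorphy columns with 3 carriers each; twelve
    group-constrained columns; BLOSUM62 background with a 3% gap rate.
    """
    blocks = [ConservedBlock(start, 16, 0.9) for start in (100, 300, 500, 700, 900)]
    inv_residues = "WPRFHKGLNDYSTMEAVQIC"  # varied residues for planted invariants
    invariant_columns: dict[int, str] = {}
    offsets = (2, 5, 8, 11, 14)
    k = 0
    for block in blocks:
        for off in offsets:
            if k >= 24:
                break
            invariant_columns[block.start + off] = inv_residues[k % len(inv_residues)]
            k += 1
    group_labels = ("aliphatic", "aromatic", "acidic", "basic", "hydroxyl", "amide")
    group_sites = (140, 220, 240, 380, 460, 540, 660, 740, 820, 940, 1020, 1060)
    group_columns = {
        col: group_labels[i % len(group_labels)] for i, col in enumerate(group_sites)
    }
    autapomorphy_columns = {col: 3 for col in (50, 170, 260, 430, 620, 790, 860, 1050)}
    return SyntheticFamilySpec(
        n_sequences=34,
        n_columns=1100,
        seed=seed,
        invariant_columns=invariant_columns,
        group_columns=group_columns,
        conserved_blocks=blocks,
        motif_plants=[MotifPlant("G6P_SxSTxxST", "SDTLFT", 600, 0.9)],
        autapomorphy_columns=autapomorphy_columns,
        indel_rate=0.03,
    )


def _sample_background(rng: np.random.Generator, size, background: np.ndarray) -> np.ndarray:
    return rng.choice(_AA_ARRAY, size=size, p=background)


def _break_consensus_collisions(
    spec: SyntheticFamilySpec, dominants: dict[int, str], rng: np.random.Generator
) -> None:
    """Resample block dominants that would let a planted motif pattern match
    family-wide outside its planted location.

    A pattern position is satisfied family-wide by: a full wildcard; an
    invariant/dominant/literal residue inside its class; or a group column
    whose whole residue class is inside it. Background columns satisfy only
    wildcards (no residue is family-wide there).
    """
    from .motifscan import builtin_library

    lib = builtin_library()
    classes_of: dict[str, tuple[frozenset, ...]] = {}
    for plant in spec.motif_plants:
        if plant.name in lib and lib[plant.name].classes is not None:
            classes_of[plant.name] = lib[plant.name].classes
        else:
            classes_of[plant.name] = tuple(frozenset(ch) for ch in plant.literal)

    def family_wide(col: int, cls: frozenset) -> bool:
        if col in spec.invariant_columns:
            return spec.invariant_columns[col] in cls
        if col in dominants:
            return dominants[col] in cls
        if col in spec.group_columns:
            return frozenset(DEFAULT_GROUPS_8[spec.group_columns[col]]) <= cls
        for p in spec.motif_plants:
            if p.col_start <= col < p.col_start + len(p.literal):
                return p.literal[col - p.col_start] in cls
        return False

    for _ in range(100):  # bounded fix-up passes
        changed = False
        for plant in spec.motif_plants:
            classes = classes_of[plant.name]
            m = len(classes)
            for start in range(spec.n_columns - m + 1):
                if start == plant.col_start:
                    continue
                if not all(
                    len(cls) == 20 or family_wide(start + k, cls)
                    for k, cls in enumerate(classes)
                ):
                    continue
                fixable = [
                    start + k
                    for k, cls in enumerate(classes)
                    if len(cls) < 20 and (start + k) in dominants
                ]
                if not fixable:
                    continue  # nothing resampleable without touching other truth
                col = fixable[0]
                cls = classes[col - start]
                pool = np.array([a for a in AA20 if a not in cls])
                dominants[col] = str(rng.choice(pool))
                changed = True
        if not changed:
            return


def simulate_family(spec: SyntheticFamilySpec) -> tuple[Alignment, GroundTruth]:
    """Emit a seeded alignment and its ground truth (self-checked)."""
    spec.validate()
    rng = np.random.default_rng(spec.seed)
    n, L = spec.n_sequences, spec.n_columns
    bg = np.asarray(spec.background, dtype=float)
    bg = bg / bg.sum()

    mat = _sample_background(rng, (n, L), bg)

    planted = np.zeros(L, dtype=bool)  # columns immune to indels and fix-ups

    # Sample per-column dominant residues for the conserved blocks, then make
    # sure the family-wide consensus (invariants + dominants + motif literals)
    # does not accidentally spell an instance of a planted motif pattern
    # outside its planted location — the planted instance must be the only
    # family-wide one for the ground truth to be consistent.
    dominants: dict[int, str] = {}
    for block in spec.conserved_blocks:
        for col in range(*block.interval):
            if col not in spec.invariant_columns:
                dominants[col] = str(rng.choice(_AA_ARRAY, p=bg))
    _break_consensus_collisions(spec, dominants, rng)

    for block in spec.conserved_blocks:
        for col in range(*block.interval):
            if col in spec.invariant_columns:
                continue
            dominant = dominants[col]
            cells = np.where(
                rng.random(n) < block.dominance,
                dominant,
                rng.choice(_AA_ARRAY[_AA_ARRAY != dominant], size=n),
            )
            mat[:, col] = cells
            planted[col] = True

    for col, label in spec.group_columns.items():
        members = np.array(list(DEFAULT_GROUPS_8[label]))
        mat[:, col] = rng.choice(members, size=n)
        planted[col] = True

    motif_carriers: dict[str, np.ndarray] = {}
    for plant in spec.motif_plants:
        k = max(1, int(round(plant.carrier_fraction * n)))
        carriers = np.sort(rng.choice(n, size=k, replace=False))
        motif_carriers[plant.name] = carriers
        for j, ch in enumerate(plant.literal):
            col = plant.col_start + j
            mat[carriers, col] = ch
            planted[col] = True

    for col, res in spec.invariant_columns.items():
        mat[:, col] = res
        planted[col] = True

    for col, carriers in spec.autapomorphy_columns.items():
        keep = rng.choice(n, size=carriers, replace=False)
        column = np.full(n, GAP, dtype="U1")
        column[keep] = _sample_background(rng, carriers, bg)
        mat[:, col] = column
        planted[col] = True

    # indels in background columns only
    if spec.indel_rate > 0:
        gaps = rng.random((n, L)) < spec.indel_rate
        gaps[:, planted] = False
        mat[gaps] = GAP

    # consistency fix-up: a column not planted as invariant must not end up
    # with a single residue type (sampling can do this by chance at high
    # dominance); flip one eligible row to a different residue.
    invariant_set = set(spec.invariant_columns)
    for col in range(L):
        if col in invariant_set or col in spec.autapomorphy_columns:
            continue
        column = mat[:, col]
        residues = set(column[column != GAP])
        if len(residues) != 1:
            continue
        only = next(iter(residues))
        eligible = np.flatnonzero(column != GAP)
        protected = {
            int(r)
            for plant in spec.motif_plants
            if plant.col_start <= col < plant.col_start + len(plant.literal)
            for r in motif_carriers[plant.name]
        }
        eligible = [r for r in eligible if r not in protected]
        if not eligible:
            continue  # every occupant carries a planted motif; leave as-is
        row = int(rng.choice(eligible))
        if col in spec.group_columns:
            pool = np.array([a for a in DEFAULT_GROUPS_8[spec.group_columns[col]] if a != only])
        else:
            pool = _AA_ARRAY[_AA_ARRAY != only]
        mat[row, col] = rng.choice(pool)

    ids = tuple(f"seq{i + 1:03d}" for i in range(n))
    rows = tuple("".join(mat[i]) for i in range(n))
    aln = Alignment(ids, rows)

    cmap = build_column_map(aln)
    motif_hits: list[tuple[str, int, int, str]] = []
    motif_intervals: dict[str, tuple[int, int]] = {}
    for plant in spec.motif_plants:
        motif_intervals[plant.name] = (plant.col_start, plant.col_start + len(plant.literal))
        for row in motif_carriers[plant.name]:
            start = cmap.column_to_residue(int(row), plant.col_start)
            end = cmap.column_to_residue(int(row), plant.col_start + len(plant.literal) - 1)
            motif_hits.append((ids[int(row)], start + 1, end + 1, plant.name))

    truth = GroundTruth(
        invariant_columns=set(invariant_set),
        conserved_blocks=[b.interval for b in spec.conserved_blocks],
        motif_hits=motif_hits,
        motif_column_intervals=motif_intervals,
        low_occupancy_columns=set(spec.autapomorphy_columns),
        group_columns=set(spec.group_columns),
    )
    _self_check(aln, spec, truth)
    return aln, truth


def _self_check(aln: Alignment, spec: SyntheticFamilySpec, truth: GroundTruth) -> None:
    mat = aln.char_matrix()
    for col, res in spec.invariant_columns.items():
        column = mat[:, col]
        occupied = column[column != GAP]
        if set(occupied) != {res}:
            raise AssertionError(f"invariant column {col} is not invariant for {res!r}")
    for col, carriers in spec.autapomorphy_columns.items():
        occ = int((mat[:, col] != GAP).sum())
        if occ != carriers:
            raise AssertionError(f"autapomorphy column {col}: occupancy {occ} != {carriers}")
    row_of = {sid: i for i, sid in enumerate(aln.ids)}
    for plant in spec.motif_plants:
        lo, hi = truth.motif_column_intervals[plant.name]
        carried = [h for h in truth.motif_hits if h[3] == plant.name]
        for seq_id, start, end, _ in carried:
            segment = "".join(mat[row_of[seq_id], lo:hi])
            if segment != plant.literal:
                raise AssertionError(f"motif {plant.name} not verbatim in {seq_id}")
            ungapped = aln.ungapped(row_of[seq_id]).residues
            if ungapped[start - 1 : end] != plant.literal:
                raise AssertionError(f"motif {plant.name}: residue coordinates wrong in {seq_id}")
    # no accidental invariants outside the planted set (among occupied ≥ 2)
    for col in range(aln.length):
        if col in truth.invariant_columns or col in spec.autapomorphy_columns:
            continue
        column = mat[:, col]
        occupied = column[column != GAP]
        if occupied.size >= 2 and len(set(occupied)) == 1:
            raise AssertionError(f"column {col}: accidental invariant slipped through")


# ---------------------------------------------------------------------------
# recovery scoring

def _interval_match(a: tuple[int, int], b: tuple[int, int]) -> bool:
    """Reciprocal overlap ≥ 50% of both intervals (half-open)."""
    lo, hi = max(a[0], b[0]), min(a[1], b[1])
    overlap = max(0, hi - lo)
    return overlap >= 0.5 * (a[1] - a[0]) and overlap >= 0.5 * (b[1] - b[0])


def _prf(n_pred: int, n_truth: int, n_match_pred: int, n_match_truth: int) -> dict:
    precision = n_match_pred / n_pred if n_pred else None
    recall = n_match_truth / n_truth if n_truth else None
    if precision and recall:
        f1 = 2 * precision * recall / (precision + recall)
    elif precision is not None and recall is not None:
        f1 = 0.0
    else:
        f1 = None
    return {"precision": precision, "recall": recall, "f1": f1,
            "n_predicted": n_pred, "n_truth": n_truth}


def recovery_report(
    predicted: dict[str, object], truth: GroundTruth
) -> dict[str, dict]:
    """Precision/recall/F1 per feature class.

    ``predicted`` may carry any of: ``invariant_columns`` (iterable of column
    indices), ``conserved_blocks`` (half-open intervals, scored by ≥ 50%
    reciprocal overlap), ``low_occupancy_columns``. Empty predictions report
    recall 0 and precision as missing (None).
    """
    report: dict[str, dict] = {}
    for key in ("invariant_columns", "low_occupancy_columns"):
        if key not in predicted:
            continue
        pred = set(int(c) for c in predicted[key])  # type: ignore[arg-type]
        true = getattr(truth, key)
        hit = len(pred & true)
        report[key] = _prf(len(pred), len(true), hit, hit)
    if "conserved_blocks" in predicted:
        pred_iv = [tuple(iv) for iv in predicted["conserved_blocks"]]  # type: ignore[union-attr]
        true_iv = [tuple(iv) for iv in truth.conserved_blocks]
        matched_pred = sum(any(_interval_match(p, t) for t in true_iv) for p in pred_iv)
        matched_true = sum(any(_interval_match(t, p) for p in pred_iv) for t in true_iv)
        report["conserved_blocks"] = _prf(len(pred_iv), len(true_iv), matched_pred, matched_true)
    if not report:
        raise ValueError("no recognized feature classes in `predicted`")
    return report
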