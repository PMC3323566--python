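"""Per-column conservation statistics for protein alignments.

Three complementary column scores are computed:

* ``H`` — Shannon entropy (bits) of the column's amino-acid proportions;
  0 for an invariant column, log2(20) ≈ 4.32 for a uniform one.
* ``H_FG`` — functional-group entropy: Shannon entropy after collapsing the
  20 residues into a small number of physicochemical categories (8 by
  default), which highlights columns that vary in identity but not in
  chemistry (e.g. an I/V/L/M column scores H_FG = 0).
* ``JS`` — Jensen–Shannon divergence (base-2, equal mixture weights) between
  the pseudocount-smoothed column distribution and a background amino-acid
  distribution, optionally blended with the mean raw score of neighbouring
  columns (a sliding-window extension rewarding runs of conserved sites).

Columns occupied by fewer than ``min_occupancy`` standard residues (sparse,
lineage-specific insertions) are flagged ``included=False`` and omitted from
quantiles, regression and window means.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .seqio import AA20, AA_INDEX, AA_SET, GAP, UNKNOWN, Alignment

LOG2_20 = float(np.log2(20.0))

#: Background amino-acid frequencies derived from the BLOSUM62 substitution
#: data, ordered as AA20 (alphabetical single-letter codes). Sums to 1.
BLOSUM62_FREQS: dict[str, float] = {
    "A": 0.074, "C": 0.025, "D": 0.054, "E": 0.054, "F": 0.047,
    "G": 0.074, "H": 0.026, "I": 0.068, "K": 0.058, "L": 0.099,
    "M": 0.025, "N": 0.045, "P": 0.039, "Q": 0.034, "R": 0.052,
    "S": 0.057, "T": 0.051, "V": 0.073, "W": 0.013, "Y": 0.032,
}

BLOSUM62_BACKGROUND = np.array([BLOSUM62_FREQS[a] for a in AA20])

#: Default 8-category physicochemical partition of the 20 amino acids.
#: Aliphatic/hydrophobic residues I, V, L, M share a group by construction.
DEFAULT_GROUPS_8: dict[str, str] = {
    "aliphatic": "AVLIM",
    "aromatic": "FWY",
    "hydroxyl": "ST",
    "amide": "NQ",
    "acidic": "DE",
    "basic": "HKR",
    "cysteine": "C",
    "conformational": "GP",
}


class ConfigError(ValueError):
    """Invalid scoring parameters or grouping definition."""


@dataclass(frozen=True)
class Grouping:
    """A labeled partition of the 20 amino acids into k ≥ 2 disjoint classes."""

    name: str
    groups: tuple[tuple[str, frozenset[str]], ...]

    def __post_init__(self) -> None:
        if len(self.groups) < 2:
            raise ConfigError("a grouping needs at least 2 classes")
        covered: set[str] = set()
        for label, members in self.groups:
            if not members:
                raise ConfigError(f"group {label!r} is empty")
            if members & covered:
                raise ConfigError(f"group {label!r} overlaps another group")
            covered |= members
        if covered != AA_SET:
            missing = sorted(AA_SET - covered)
            extra = sorted(covered - AA_SET)
            raise ConfigError(f"grouping must cover the 20 amino acids exactly "
                              f"(missing {missing}, extra {extra})")

    @property
    def k(self) -> int:
        return len(self.groups)

    def group_index(self) -> np.ndarray:
        """(20,) array mapping AA20 position -> group ordinal."""
        idx = np.empty(20, dtype=int)
        for g, (_, members) in enumerate(self.groups):
            for aa in members:
                idx[AA_INDEX[aa]] = g
        return idx

    @classmethod
    def from_dict(cls, mapping: dict[str, str], name: str = "custom") -> "Grouping":
        return cls(name, tuple((k, frozenset(v.upper())) for k, v in mapping.items()))

    @classmethod
    def from_file(cls, path: str | Path) -> "Grouping":
        """Parse a key-value grouping file: ``label: AVLIM`` or ``label = AVLIM``
        per line; '#' starts a comment."""
        mapping: dict[str, str] = {}
        for lineno, raw in enumerate(Path(path).read_text().splitlines(), 1):
            line = raw.split("#", 1)[0].strip()
            if not line:
                continue
            for sep in (":", "="):
                if sep in line:
                    label, members = line.split(sep, 1)
                    break
            else:
                raise ConfigError(f"{path}:{lineno}: expected 'label: RESIDUES'")
            mapping[label.strip()] = members.strip().replace(" ", "")
        return cls.from_dict(mapping, name=Path(path).stem)


def default_grouping() -> Grouping:
    return Grouping.from_dict(DEFAULT_GROUPS_8, name="physicochemical-8")


@dataclass(frozen=True)
class CountVector:
    """Residue counts of one alignment column.

    ``counts`` covers the 20 standard residues (AA20 order); gaps never
    count, and unknown residues (X) are tallied separately in ``n_unknown``.
    ``occupancy`` is the number of standard residues.
    """

    counts: np.ndarray
    n_unknown: int = 0

    @property
    def occupancy(self) -> int:
        return int(self.counts.sum())


@dataclass(frozen=True)
class JsParams:
    """Jensen–Shannon scoring parameters.

    window
        neighbour radius (columns) for the sliding-window blend; 0 disables it.
    weight
        mixing weight w in [0,1] on the neighbour mean:
        ``JS = (1-w)*JS_raw + w*mean(JS_raw of included neighbours)``.
    background
        probability vector over the 20 amino acids (AA20 order).
    pseudocount
        small mass added to each column proportion before the divergence.
    """

    background: np.ndarray = field(default_factory=lambda: BLOSUM62_BACKGROUND.copy())
    window: int = 3
    weight: float = 0.5
    pseudocount: float = 1e-7

    def __post_init__(self) -> None:
        bg = np.asarray(self.background, dtype=float)
        if bg.shape != (20,) or np.any(bg < 0) or not np.isclose(bg.sum(), 1.0):
            raise ConfigError("background must be a 20-vector of probabilities summing to 1")
        object.__setattr__(self, "background", bg)
        if self.window < 0 or not 0.0 <= self.weight <= 1.0 or self.pseudocount < 0:
            raise ConfigError("window ≥ 0, weight in [0,1], pseudocount ≥ 0 required")


@dataclass(frozen=True)
class ThresholdSet:
    """Filters and cut-offs used across the pipeline (defaults as analysed)."""

    js_percentile: float = 0.90
    h_conserved: float = 2.0      # bits; "highly conserved" entropy cut
    hfg_conserved: float = 0.1    # bits; functional-entropy conservation cut
    min_occupancy: int = 10       # strict: columns with < 10 residues excluded

    def __post_init__(self) -> None:
        if not 0.0 < self.js_percentile < 1.0:
            raise ConfigError("js_percentile must be in (0,1)")
        if self.min_occupancy < 1:
            raise ConfigError("min_occupancy must be ≥ 1")


@dataclass(frozen=True)
class RegressionFit:
    intercept: float
    slope: float
    r2: float


@dataclass
class ConservationProfile:
    """Per-column statistics; excluded columns carry NaN downstream."""

    occupancy: np.ndarray   # (L,) int
    H: np.ndarray           # (L,) float, NaN where occupancy == 0
    H_FG: np.ndarray        # (L,) float
    JS_raw: np.ndarray      # (L,) float
    JS: np.ndarray          # (L,) float (windowed)
    included: np.ndarray    # (L,) bool

    def __len__(self) -> int:
        return len(self.occupancy)

    def to_frame(self) -> pd.DataFrame:
        """Per-site table; ``column`` is 1-based for reporting."""
        return pd.DataFrame(
            {
                "column": np.arange(1, len(self) + 1),
                "occupancy": self.occupancy,
                "H": self.H,
                "H_FG": self.H_FG,
                "JS_raw": self.JS_raw,
                "JS": self.JS,
                "included": self.included,
            }
        )


# ---------------------------------------------------------------------------
# column counts

def count_matrix(aln: Alignment) -> np.ndarray:
    """(L, 20) matrix of per-column residue counts (gaps/unknowns excluded)."""
    mat = aln.char_matrix()
    counts = np.empty((aln.length, 20), dtype=np.int64)
    for i, aa in enumerate(AA20):
        counts[:, i] = (mat == aa).sum(axis=0)
    return counts


def unknown_counts(aln: Alignment) -> np.ndarray:
    return (aln.char_matrix() == UNKNOWN).sum(axis=0)


def column_counts(aln: Alignment, col: int) -> CountVector:
    """Residue counts for one column (0-based index)."""
    if not 0 <= col < aln.length:
        raise IndexError(f"column {col} outside [0, {aln.length})")
    column = aln.column(col)
    counts = np.zeros(20, dtype=np.int64)
    n_unknown = 0
    for ch in column:
        if ch == GAP:
            continue
        if ch == UNKNOWN:
            n_unknown += 1
        else:
            counts[AA_INDEX[ch]] += 1
    return CountVector(counts=counts, n_unknown=n_unknown)


# ---------------------------------------------------------------------------
# entropies

def _entropy_bits(counts: np.ndarray) -> float:
    total = counts.sum()
    if total <= 0:
        return float("nan")
    p = counts[counts > 0] / total
    return float(-(p * np.log2(p)).sum())


def shannon_entropy(cv: CountVector) -> float:
    """Shannon entropy H = -Σ p_a log2 p_a in bits; NaN for empty columns."""
    return _entropy_bits(cv.counts)


def functional_group_entropy(cv: CountVector, grouping: Grouping | None = None) -> float:
    """Shannon entropy of the group-collapsed counts (bits)."""
    grouping = grouping or default_grouping()
    gidx = grouping.group_index()
    gcounts = np.bincount(gidx, weights=cv.counts, minlength=grouping.k)
    return _entropy_bits(gcounts)


# ---------------------------------------------------------------------------
# Jensen–Shannon score

def _kl_bits(p: np.ndarray, q: np.ndarray) -> float:
    mask = p > 0
    return float((p[mask] * np.log2(p[mask] / q[mask])).sum())


def js_score(cv: CountVector, params: JsParams | None = None) -> float:
    """Raw Jensen–Shannon divergence of a column versus the background.

    Base-2 logs and equal mixture weights, so the result lies in [0, 1]:
    1 marks a column maximally distinct from the background (a single
    residue type the background rarely uses), 0 an exact background match.
    """
    params = params or JsParams()
    if cv.occupancy < 1:
        return float("nan")
    p = cv.counts / cv.occupancy
    if params.pseudocount > 0:
        p = p + params.pseudocount
        p = p / p.sum()
    q = params.background
    m = 0.5 * (p + q)
    return 0.5 * _kl_bits(p, m) + 0.5 * _kl_bits(q, m)


def _raw_js_vector(counts: np.ndarray, params: JsParams) -> np.ndarray:
    occ = counts.sum(axis=1)
    out = np.full(len(counts), np.nan)
    for c in np.flatnonzero(occ > 0):
        out[c] = js_score(CountVector(counts=counts[c]), params)
    return out


def windowed_js(
    aln: Alignment,
    params: JsParams | None = None,
    thresholds: ThresholdSet | None = None,
) -> ConservationProfile:
    """Full conservation profile with the window-blended JS score.

    ``JS(c) = (1-w)*JS_raw(c) + w * mean(JS_raw over included columns within
    ±window of c, c itself excluded)``. The window truncates at the alignment
    ends; low-occupancy columns are omitted from neighbour means; a column
    with no included neighbour keeps its raw score.
    """
    params = params or JsParams()
    thresholds = thresholds or ThresholdSet()
    counts = count_matrix(aln)
    occ = counts.sum(axis=1)
    included = occ >= thresholds.min_occupancy

    gidx = default_grouping().group_index()
    L = aln.length
    H = np.full(L, np.nan)
    H_FG = np.full(L, np.nan)
    for c in np.flatnonzero(occ > 0):
        H[c] = _entropy_bits(counts[c])
        H_FG[c] = _entropy_bits(np.bincount(gidx, weights=counts[c], minlength=20))

    js_raw = _raw_js_vector(counts, params)
    js = js_raw.copy()
    w, radius = params.weight, params.window
    if w > 0 and radius > 0:
        for c in range(L):
            if np.isnan(js_raw[c]):
                continue
            lo, hi = max(0, c - radius), min(L, c + radius + 1)
            neigh = [j for j in range(lo, hi) if j != c and included[j] and not np.isnan(js_raw[j])]
            if neigh:
                js[c] = (1.0 - w) * js_raw[c] + w * float(np.mean(js_raw[neigh]))
    return ConservationProfile(
        occupancy=occ, H=H, H_FG=H_FG, JS_raw=js_raw, JS=js, included=included
    )


def conservation_profile(
    aln: Alignment,
    params: JsParams | None = None,
    grouping: Grouping | None = None,
    thresholds: ThresholdSet | None = None,
) -> ConservationProfile:
    """Counts → entropies → occupancy filter → windowed JS, in one call."""
    profile = windowed_js(aln, params, thresholds)
    if grouping is not None and grouping.groups != default_grouping().groups:
        counts = count_matrix(aln)
        gidx = grouping.group_index()
        for c in np.flatnonzero(profile.occupancy > 0):
            profile.H_FG[c] = _entropy_bits(
                np.bincount(gidx, weights=counts[c], minlength=grouping.k)
            )
    return profile


# ---------------------------------------------------------------------------
# filters, thresholds, detection

def occupancy_filter(
    profile: ConservationProfile, thresholds: ThresholdSet | None = None
) -> ConservationProfile:
    """Mark columns with occupancy < min_occupancy as excluded (strict <)."""
    thresholds = thresholds or ThresholdSet()
    return replace(profile, included=profile.occupancy >= thresholds.min_occupancy)


def invariant_sites(aln: Alignment, thresholds: ThresholdSet | None = None) -> list[int]:
    """Included columns containing exactly one residue type (H = 0).

    Returns 0-based column indices; add 1 for reporting.
    """
    thresholds = thresholds or ThresholdSet()
    counts = count_matrix(aln)
    occ = counts.sum(axis=1)
    single = (counts > 0).sum(axis=1) == 1
    return [int(c) for c in np.flatnonzero((occ >= thresholds.min_occupancy) & single)]


def js_threshold(profile: ConservationProfile, q: float = 0.90) -> float:
    """Nearest-rank empirical q-quantile of JS over included columns.

    The threshold is the ceil(q*n)-th smallest included JS value; "top
    sites" downstream are those **strictly** greater.
    """
    if not 0.0 < q < 1.0:
        raise ConfigError("quantile must be in (0,1)")
    vals = profile.JS[profile.included & ~np.isnan(profile.JS)]
    if vals.size == 0:
        raise ValueError("no included columns: cannot take a quantile")
    order = np.sort(vals)
    rank = int(np.ceil(q * order.size))  # 1-based nearest rank
    return float(order[max(rank, 1) - 1])


def entropy_js_regression(profile: ConservationProfile) -> RegressionFit:
    """OLS of JS (response) on H (predictor) over included columns."""
    mask = profile.included & ~np.isnan(profile.H) & ~np.isnan(profile.JS)
    x, y = profile.H[mask], profile.JS[mask]
    if x.size < 3:
        raise ValueError("need at least 3 included columns for a regression")
    if np.allclose(x, x[0]):
        raise ValueError("zero variance in H: regression undefined")
    fit = stats.linregress(x, y)
    # a constant response has zero correlation (linregress yields NaN there)
    r2 = 0.0 if np.isnan(fit.rvalue) else float(fit.rvalue**2)
    return RegressionFit(intercept=float(fit.intercept), slope=float(fit.slope), r2=r2)


def segment_conserved_regions(
    profile: ConservationProfile, threshold: float, min_run: int = 5
) -> list[tuple[int, int]]:
    """Maximal runs of ≥ min_run consecutive included columns with JS > threshold.

    Returned as 0-based half-open column intervals.
    """
    above = profile.included & (profile.JS > threshold)
    intervals: list[tuple[int, int]] = []
    start = None
    for c, flag in enumerate(above):
        if flag and start is None:
            start = c
        elif not flag and start is not None:
            if c - start >= min_run:
                intervals.append((start, c))
            start = None
    if start is not None and len(above) - start >= min_run:
        intervals.append((start, len(above)))
    return intervals


def logo_counts(aln: Alignment, interval: tuple[int, int]) -> pd.DataFrame:
    """Position × residue count matrix for a column interval (0-based half-open).

    Column sums equal per-column occupancy; information content per position
    is log2(20) - H. Suitable for sequence-logo rendering.
    """
    start, end = interval
    if not (0 <= start < end <= aln.length):
        raise IndexError(f"interval {interval} outside alignment of length {aln.length}")
    counts = count_matrix(aln)[start:end]
    return pd.DataFrame(counts, index=np.arange(start + 1, end + 1), columns=list(AA20))


# ---------------------------------------------------------------------------
# tabular output

def write_profile_tsv(
    profile: ConservationProfile, path: str | Path, thresholds: ThresholdSet | None = None
) -> None:
    """Per-site TSV with invariant/conserved flags appended."""
    thresholds = thresholds or ThresholdSet()
    frame = profile.to_frame()
    frame["invariant"] = profile.included & (profile.H == 0.0)
    frame["h_conserved"] = profile.included & (profile.H < thresholds.h_conserved)
    frame["hfg_conserved"] = profile.included & (profile.H_FG < thresholds.hfg_conserved)
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def write_intervals_bed(
    intervals: Sequence[tuple[int, int]],
    path: str | Path,
    chrom: str = "alignment",
    labels: Sequence[str] | None = None,
) -> None:
    """BED (0-based half-open, alignment-column space) with region labels."""
    with open(path, "w") as fh:
        for i, (start, end) in enumerate(intervals):
            name = labels[i] if labels else f"region_{i + 1}"
            fh.write(f"{chrom}\t{start}\t{end}\t{name}\n")
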