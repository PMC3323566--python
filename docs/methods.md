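# Methods

## Column statistics

All statistics operate on one alignment column at a time. Gaps are never
counted; the unknown residue `X` is tallied separately and contributes
neither to occupancy nor to any distribution (an `X` is evidence that a
residue is present but not of its identity; since the occupancy filter is
meant to remove columns with too little *identity* evidence, `X` is kept out
of occupancy as well). Occupancy is therefore the number of standard
residues in the column.

**Entropy.** `H = -Σ p_a log2 p_a` with `p_a = count_a / occupancy`. Base-2
logs throughout, so `H` ranges over [0, log2 20 ≈ 4.3219] bits and the
conventional "highly conserved" cut `H < 2.0` sits near the middle of the
scale. Functional-group entropy `H_FG` applies the same formula to counts
summed within a partition of the alphabet. The shipped default has eight
physicochemical classes — aliphatic {AVLIM}, aromatic {FWY}, hydroxyl {ST},
amide {NQ}, acidic {DE}, basic {HKR}, cysteine {C}, conformational {GP}.
The exact composition of eight-class schemes varies across the literature;
this one is a documented choice (config-overridable via a key-value file)
whose essential property is that the aliphatic hydrophobics I, V, L, M share
a class, so chemically constrained but identity-variable columns score
`H_FG ≈ 0`. Coarsening a partition can only lose information, so
`H_FG ≤ H` always. Empty columns return NaN rather than 0: zero entropy
means "invariant", which an empty column is not.

**Jensen–Shannon score.** `JS_raw` is the base-2 Jensen–Shannon divergence
with equal mixture weights between the column distribution and a background
distribution, which bounds it in [0, 1]. Defaults: BLOSUM62 amino-acid
frequencies as background, pseudocount 1e-7 added to the column proportions
(then renormalized) so the divergence is insensitive to zero cells, window
radius 3 and mixing weight w = 0.5 for the windowed extension

    JS(c) = (1-w) * JS_raw(c) + w * mean{ JS_raw(j) : |j-c| <= 3, j != c, j included }

following the published conventions of the window-extended JS conservation
heuristic this score family comes from. The window truncates at the
alignment ends; excluded (low-occupancy) columns are omitted from neighbour
means; a column with no included neighbour keeps its raw score. All four
parameters are exposed in `JsParams`. Because the window, weight, background
and pseudocount of any given published JS analysis are rarely stated,
absolute JS values (and quantile thresholds derived from them) are
comparable only within a parameterization, never across tools; this package
therefore validates JS behaviour by properties and oracles, not by matching
any external threshold value.

**Filters and detection.** The occupancy filter is strict: a column is
excluded when it holds fewer than `min_occupancy = 10` residues; excluded
columns keep their raw statistics but are omitted from quantiles, the
regression and neighbour means. Invariant sites are included columns with
exactly one residue type (equivalently `H = 0`). The JS threshold is the
nearest-rank empirical quantile (the `ceil(q·n)`-th order statistic) and
"top sites" are strictly above it, so an all-equal profile has zero top
sites. Conserved regions are maximal runs of at least `min_run = 5`
consecutive included columns strictly above the threshold; an excluded
column breaks a run. The regression is ordinary least squares of JS
(response) on H (predictor) over included columns — transpose the variables
yourself if you want the other orientation; `r²` is defined as 0 when the
response has no variance.

## Motif engine

Two dialects, one hit model. The `braces-exclusion` dialect is fixed-length:
each token — `[...]` (permitted set), `{...}` (prohibited set, i.e. the
complement), a literal, or `x`/`.` (any of the 20) — matches exactly one
residue, and the pattern compiles to one residue class per position. The
`elm` dialect is ordinary regular-expression syntax. Overlapping scans try a
match at every start; for variable-length elm patterns the match reported at
each start is the leftmost-longest one, found by trying anchored lengths
from the longest downward (greedy regex backtracking alone does not
guarantee longest-overall). Scanning always operates on the ungapped
sequence; alignment scans back-map hits through the column map, so a hit
whose residues straddle a gap reports the full spanned column interval. The
consensus track reports, per column, the fraction of sequences with a hit
covering that column (optionally within a ± window), which separates
family-wide motif occurrences from sporadic background matches.

Three of the built-in signatures (`MCRIII_ext`, `CRS_MCRIV`, `MCRI_core`)
are canonicalized from typographically emphasized/spaced forms to contiguous
patterns with `x` wildcards; emphasis carries no match semantics. The
`CRS_MCRIV` canonicalization `VxxEY[KH]KWRx[FY][FY][KR]` is a reading of an
ambiguously spaced source and is kept as a single contiguous pattern.

One caveat is recorded permanently in the test suite: the widely reproduced
nine-residue transactivation-domain regex
`[GSTDENQWYM]{KRHCGP}[FLIVMW]{KRHCGP}{CGP}{KRHCGP}[FLIVMW][FLIVAMW]{KRHCP}`
rejects the peptide `DTLFSTLSS` (its eighth residue, S, is not in
`[FLIVAMW]`), even though that peptide is commonly cited as a second
overlapping instance in the MondoA MCR6 region. The engine implements the
printed pattern faithfully; the corresponding worked-example test case fails
by design and documents the discrepancy rather than papering over it with a
loosened pattern.

## Structure annotation

The helical wheel uses the ideal α-helix geometry only: 100° per residue
(3.6 residues/turn), `angle(i) = ((i-1)·100) mod 360`. No hydrophobic
moment is computed — face membership is what the projection is for, and
residues on a common face sit within ~50° of each other. Chemical-identity
flags mark columns whose modal functional group covers at least 75% of
occupancy (an alignment-level analogue of "chemical similarity" shading).

The proline/glutamine-rich region scanner replaces an opaque external
rich-region predictor with a transparent rule: flag every window of length
25 whose target-residue share reaches 0.35, merge overlapping flagged
windows, trim the merged span to start and end on the target residue, and
recompute the fraction over the span. A central region classifies as
proline (checked first) or glutamine when a rich interval of ≥ 25 residues
lies inside it, else neither. The 25/0.35/25 defaults give, on uniform
background (residue frequency ~5%), a per-window false-flag probability
around 1e-7, while a genuine compositional bias (≥ 50% target) is detected
essentially always; all three are parameters.

## Synthetic families

The generator samples sequences independently given per-column
distributions (a star phylogeny). Tree-structured evolution, realistic
indel processes and rate heterogeneity are deliberately out of scope: every
downstream statistic is column-wise, so correlated ancestry would change
the variance of the estimates but not the identity of the planted features,
and modelling it would buy no additional test power here. Consequently,
passing recovery tests show the pipeline's operations are correct on data
with the right column-level structure; they do not show robustness to
phylogenetic autocorrelation or alignment error in real families.

Canonical conditions (`default_family_spec`): 34 sequences × 1,100 columns;
five 16-column conserved blocks (per-column dominant residue carried with
probability 0.9) containing the 24 planted invariant columns; one 6-residue
motif instance (`SDTLFT`, matching the Sx[ST]xx[ST] signature) planted at a
fixed column block in 90% of sequences; eight autapomorphy columns occupied
by 3 sequences each; twelve group-constrained columns; BLOSUM62 background
with a 3% per-cell gap rate in background columns. These sizes mirror the
scale of a deep metazoan family analysis (a few dozen species, ~1,000
columns, ~2% invariant sites) and keep the full pipeline run to seconds.

Ground-truth consistency is enforced, not assumed, at emission:

- invariant columns are written as a single residue across all rows and
  autapomorphy occupancies are checked exactly;
- a column *not* planted as invariant that ends up single-residue by chance
  has one non-protected cell resampled to a different residue (within the
  group for group-constrained columns);
- block dominants are resampled if the family-wide consensus they create
  (together with invariant and literal-motif columns) would spell an
  instance of any planted motif's pattern outside its planted window —
  with 80 block columns at 0.9 dominance this happens by chance in a few
  percent of seeds and would otherwise contradict the planted truth that
  the motif is family-wide only at its planted location.

A single `numpy` generator stream seeded by the spec's integer seed drives
every draw, so emission is byte-identical across runs; the fix-ups above
consume from the same stream and are equally deterministic.

Recovery is scored as precision/recall/F1 per feature class; point features
(columns) by set intersection, intervals by ≥ 50% reciprocal overlap. An
empty prediction reports recall 0 and a missing (None) precision.

The emulated entropy structure is checked in the suite: included-column
entropies are bimodal (conserved vs background mode), tested with a
1-versus-2-component Gaussian-mixture BIC comparison, and the JS-on-H
regression slope is negative, as in real mixed conserved/variable
alignments.

## Numerical and interface choices

- Internal coordinates are 0-based half-open everywhere; every user-facing
  report (TSV, hits, CLI) is 1-based inclusive, except BED output, which is
  0-based half-open per the format.
- Gap characters `-` and `.` are accepted on input and normalized to `-`;
  case is canonicalized to upper.
- Nearest-rank quantiles (no interpolation) keep thresholds equal to an
  observed score, which makes the strict-inequality "above threshold" rule
  well defined.
- `scripts/acceptance.py` reduces the seed modulo 2^31 before use.

## Known limitations

- No phylogenetic weighting or rate estimation: closely related sequences
  are counted as independent observations, which overstates conservation in
  clade-heavy samples.
- Absolute JS values depend on the window/weight/background/pseudocount
  parameterization (see above) and should not be compared across tools.
- The motif engine is pattern-based only; no PSSM or profile-HMM scoring.
- The compositional-bias rule is a transparent stand-in for richer
  low-complexity detectors and is validated on synthetic plants only.
- Alignments are consumed as given; building or merging them is out of
  scope.
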