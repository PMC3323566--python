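"""Independent reference implementations used only to check the package.

Each oracle recomputes a quantity through a different route than the
implementation under test: direct formula evaluation, brute-force
enumeration, or closed-form algebra.
"""

import numpy as np
from scipy.spatial.distance import jensenshannon

from mondocons.seqio import AA20, AA_SET


def jsd_oracle(p, q):
    """Base-2 Jensen–Shannon divergence via scipy's distance (sqrt of JSD)."""
    return float(jensenshannon(p, q, base=2) ** 2)


def entropy_oracle(counts):
    """Direct -sum p log2 p."""
    total = sum(counts)
    h = 0.0
    for c in counts:
        if c > 0:
            p = c / total
            h -= p * np.log2(p)
    return h


def windowed_oracle(js_raw, included, window, weight):
    """Brute-force neighbour averaging of raw JS scores.

    Mirrors the documented definition: neighbours are included columns
    within +/- window, the centre column excluded; a column with no
    included neighbour keeps its raw score.
    """
    out = []
    n = len(js_raw)
    for c in range(n):
        if np.isnan(js_raw[c]):
            out.append(np.nan)
            continue
        neigh = [
            js_raw[j]
            for j in range(max(0, c - window), min(n, c + window + 1))
            if j != c and included[j] and not np.isnan(js_raw[j])
        ]
        if neigh and weight > 0 and window > 0:
            out.append((1 - weight) * js_raw[c] + weight * float(np.mean(neigh)))
        else:
            out.append(js_raw[c])
    return np.array(out)


def ols_oracle(x, y):
    """Closed-form normal-equations OLS of y on x, plus r^2."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    X = np.column_stack([np.ones_like(x), x])
    beta = np.linalg.solve(X.T @ X, X.T @ y)
    resid = y - X @ beta
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return float(beta[0]), float(beta[1]), r2


def parse_position_classes(pattern):
    """Independent parse of a braces-exclusion pattern into residue sets."""
    classes = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            classes.append(set(pattern[i + 1 : j]))
            i = j + 1
        elif ch == "{":
            j = pattern.index("}", i)
            classes.append(set(AA_SET) - set(pattern[i + 1 : j]))
            i = j + 1
        elif ch in "xX.":
            classes.append(set(AA_SET))
            i += 1
        else:
            classes.append({ch.upper()})
            i += 1
    return classes


def brute_force_scan(sequence, classes):
    """All (start, end) 1-based inclusive matches by per-position set checks."""
    n, m = len(sequence), len(classes)
    hits = []
    for i in range(n - m + 1):
        if all(sequence[i + k] in classes[k] for k in range(m)):
            hits.append((i + 1, i + m))
    return hits


def expand_elm_fixed(pattern):
    """Expand an elm-subset pattern into all fixed-length class sequences.

    Handles classes, literals, '.' and {m[,n]} quantifiers by enumeration,
    giving an oracle for variable-length patterns that is independent of any
    regex engine. Returns a list of class-sequences (each a list of sets).
    """
    tokens = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            j = pattern.index("]", i)
            cls = set(pattern[i + 1 : j])
            i = j + 1
        elif ch == ".":
            cls = set(AA_SET)
            i += 1
        else:
            cls = {ch.upper()}
            i += 1
        lo = hi = 1
        if i < len(pattern) and pattern[i] == "{":
            j = pattern.index("}", i)
            body = pattern[i + 1 : j]
            if "," in body:
                a, b = body.split(",")
                lo, hi = int(a), int(b)
            else:
                lo = hi = int(body)
            i = j + 1
        tokens.append((cls, lo, hi))

    expansions = [[]]
    for cls, lo, hi in tokens:
        new = []
        for prefix in expansions:
            for count in range(lo, hi + 1):
                new.append(prefix + [cls] * count)
        expansions = new
    return expansions


def brute_force_elm_scan(sequence, pattern):
    """Longest match at each start over all fixed-length expansions."""
    best = {}
    for classes in expand_elm_fixed(pattern):
        for start, end in brute_force_scan(sequence, classes):
            if end > best.get(start, -1):
                best[start] = end
    return sorted(best.items())
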