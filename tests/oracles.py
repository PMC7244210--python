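"""Independent brute-force oracles used to cross-check the implementation.

Everything here is deliberately written with explicit loops and
elementary formulas — no calls into clustercore and no shared helper
code — so agreement with the package is meaningful.
"""

from __future__ import annotations

import math
from itertools import product


# -- quantiles ----------------------------------------------------------


def quantile_sorted(values, q):
    """Linear-interpolation quantile on a sorted copy (classic type-7)."""
    xs = sorted(float(v) for v in values)
    n = len(xs)
    if n == 1:
        return xs[0]
    h = (n - 1) * q
    lo = math.floor(h)
    hi = min(lo + 1, n - 1)
    return xs[lo] + (h - lo) * (xs[hi] - xs[lo])


def top_percentile(values, top):
    return quantile_sorted(values, (100.0 - top) / 100.0)


# -- log10 statistics ---------------------------------------------------


def log_positive(matrix_rows):
    out = []
    for row in matrix_rows:
        for v in row:
            if v > 0:
                out.append(math.log10(v))
    return out


def mean(xs):
    return sum(xs) / len(xs)


def sd(xs):
    m = mean(xs)
    return math.sqrt(sum((x - m) ** 2 for x in xs) / len(xs))


# -- cluster-specific threshold equations -------------------------------


def cluster_threshold_chain(values_by_cluster):
    """Full chain: stats → raw θ → normalised Θ → resolved cutoffs.

    ``values_by_cluster``: {cluster: list of rows (one per enzyme) of
    linear-scale values}.  Returns (stats, theta, Theta, cutoffs) where
    stats = {c: (mu, sigma)} plus dataset (M, Delta) under key None.
    """
    pooled = {c: log_positive(rows) for c, rows in values_by_cluster.items()}
    allv = [x for xs in pooled.values() for x in xs]
    M, Delta = mean(allv), sd(allv)
    stats = {c: (mean(xs), sd(xs)) for c, xs in pooled.items()}

    diffs = {c: stats[c][1] - Delta for c in stats}
    denom = max(diffs.values())
    theta = {}
    for c in stats:
        f = 0.0 if denom == 0 else diffs[c] / denom
        g = -(stats[c][0] - M)
        theta[c] = f + g

    tmin, tmax = min(theta.values()), max(theta.values())
    if tmax == tmin:
        Theta = {c: 100.0 for c in theta}
    else:
        Theta = {c: (theta[c] - tmin) * 100.0 / (tmax - tmin) for c in theta}

    cutoffs = {}
    for c in Theta:
        if Theta[c] >= 100.0 - 1e-9:
            cutoffs[c] = M
        else:
            cutoffs[c] = top_percentile(pooled[c], Theta[c])
    return (stats, (M, Delta)), theta, Theta, cutoffs


# -- extraction-method input equations ----------------------------------


def threshold_distances(values, cutoffs_per_enzyme, zero_floor):
    """D = log10(x) - cutoff, with zeros at the floor."""
    out = []
    for row, cut in zip(values, cutoffs_per_enzyme):
        out.append(
            [
                (math.log10(v) if v > 0 else zero_floor) - cut
                for v in row
            ]
        )
    return out


def ubiquity(D):
    flat = [d for row in D for d in row]
    negs = [d for d in flat if d < 0]
    if not negs:
        return [[1.0 for _ in row] for row in D]
    dmin = min(negs)
    return [
        [1.0 if d >= 0 else 1.0 - d / dmin for d in row] for row in D
    ]


def init_enzyme_weights(D):
    dmax = max(abs(d) for row in D for d in row)
    if dmax == 0:
        return [[0.0 for _ in row] for row in D]
    return [[d / dmax for d in row] for row in D]


# -- evaluation statistics ----------------------------------------------


def hypergeom_upper_tail(k, N, K, n):
    """P(X >= k) for X ~ Hypergeom(N, K, n) by exact enumeration."""
    total = math.comb(N, n)
    acc = 0
    for x in range(k, min(K, n) + 1):
        if n - x <= N - K:
            acc += math.comb(K, x) * math.comb(N - K, n - x)
    return acc / total


def gini_pairwise(xs):
    """Normalised Gini via the mean-absolute-difference definition."""
    n = len(xs)
    m = sum(xs) / n
    if m == 0:
        return None
    mad = sum(abs(a - b) for a in xs for b in xs) / (n * n)
    return (mad / (2.0 * m)) * n / (n - 1.0)


# -- boolean rule evaluation --------------------------------------------


def eval_rule(rule, true_genes):
    """Evaluate a GPR rule string under a truth assignment (python syntax)."""
    if not rule.strip():
        return False
    expr = rule
    names = sorted(set(_rule_genes(rule)), key=len, reverse=True)
    env = {g: (g in true_genes) for g in names}
    return bool(eval(expr, {"__builtins__": {}}, env))  # noqa: S307 - test oracle


def _rule_genes(rule):
    import re

    return [
        t
        for t in re.findall(r"[A-Za-z0-9_.]+", rule)
        if t not in {"and", "or"}
    ]


def clauses_equivalent(rule, clauses, genes=None):
    """Exhaustively check DNF clauses against the original rule."""
    genes = sorted(set(genes if genes is not None else _rule_genes(rule)))
    for bits in product([False, True], repeat=len(genes)):
        true_genes = {g for g, b in zip(genes, bits) if b}
        direct = eval_rule(rule, true_genes)
        via_dnf = any(set(c) <= true_genes for c in clauses)
        if direct != via_dnf:
            return False
    return True
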