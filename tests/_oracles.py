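"""Independent reference implementations used only to check the package.

Each oracle is written from first principles (brute force, enumeration, or
closed form) and deliberately avoids the code paths it validates.
"""

from __future__ import annotations

import math
import statistics
from fractions import Fraction

import numpy as np
from scipy import optimize, special, stats


def ebayes_oracle(diffs: np.ndarray) -> dict:
    """Moderated paired t straight from the formulas.

    The trigamma equation is solved by bracketing/bisection (brentq), not
    Newton; the rest follows the moment-matching definitions literally.
    """
    n = diffs.shape[1]
    d = n - 1
    mean = diffs.mean(axis=1)
    s2 = diffs.var(axis=1, ddof=1)
    z = np.log(s2)
    e = z - special.digamma(d / 2.0) + math.log(d / 2.0)
    evar = e.var(ddof=1) - special.polygamma(1, d / 2.0)
    if evar > 0:
        y = optimize.brentq(lambda v: special.polygamma(1, v) - evar, 1e-8, 1e10)
        d0 = 2.0 * y
        s0 = math.exp(e.mean() + special.digamma(y) - math.log(y))
        post = (d0 * s0 + d * s2) / (d0 + d)
        t = mean / np.sqrt(post / n)
        p = 2.0 * stats.t.sf(np.abs(t), d + d0)
    else:
        d0 = np.inf
        s0 = math.exp(e.mean())
        post = np.full_like(s2, s0)
        t = mean / np.sqrt(post / n)
        p = 2.0 * stats.norm.sf(np.abs(t))
    return {"d0": d0, "s0": s0, "post": post, "t": t, "p": p}


def brute_force_clusters(positions, maxgap):
    """Transitive closure of the 'within maxgap' relation via union-find.

    Pairs are examined in sorted order; once the gap from position i
    exceeds maxgap the remaining (larger) positions cannot be adjacent to
    it, which prunes the O(n^2) scan without changing the closure.
    """
    positions = sorted(positions)
    n = len(positions)
    parent = list(range(n))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(n):
        for j in range(i + 1, n):
            if positions[j] - positions[i] > maxgap:
                break
            parent[find(i)] = find(j)
    groups = {}
    for i in range(n):
        groups.setdefault(find(i), []).append(positions[i])
    return sorted(tuple(sorted(g)) for g in groups.values())


def median_polish_oracle(matrix, tol=1e-6, max_iter=10):
    """Loop-based median polish using statistics.median (no numpy medians)."""
    resid = [list(map(float, row)) for row in matrix]
    nr, nc = len(resid), len(resid[0])
    overall = 0.0
    row_eff = [0.0] * nr
    col_eff = [0.0] * nc
    for _ in range(max_iter):
        delta = 0.0
        for i in range(nr):
            m = statistics.median(resid[i])
            for j in range(nc):
                resid[i][j] -= m
            row_eff[i] += m
            delta += abs(m)
        m = statistics.median(row_eff)
        row_eff = [r - m for r in row_eff]
        overall += m
        for j in range(nc):
            m = statistics.median([resid[i][j] for i in range(nr)])
            for i in range(nr):
                resid[i][j] -= m
            col_eff[j] += m
            delta += abs(m)
        m = statistics.median(col_eff)
        col_eff = [c - m for c in col_eff]
        overall += m
        if delta < tol:
            break
    return overall, row_eff, col_eff, resid


def fisher_oracle(a, b, c, d):
    """Two-tailed Fisher p by enumerating all tables with the same margins.

    Exact rational hypergeometric probabilities; a table contributes when
    its probability is <= the observed table's (exact comparison).
    """
    r1, r2 = a + b, c + d
    c1 = a + c
    n = r1 + r2

    def pmf(x):
        return Fraction(math.comb(r1, x) * math.comb(r2, c1 - x), math.comb(n, c1))

    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    p_obs = pmf(a)
    total = sum(pmf(x) for x in range(lo, hi + 1) if pmf(x) <= p_obs)
    return float(total)


def brute_threshold(int_matrix: np.ndarray, background, p_cutoff):
    """Score threshold by exhaustive enumeration of all 4^L sequences."""
    L = int_matrix.shape[1]
    scores = np.zeros(1, dtype=np.int64)
    weights = np.ones(1)
    for j in range(L):
        scores = (scores[:, None] + int_matrix[:, j][None, :]).ravel()
        weights = (weights[:, None] * np.asarray(background)[None, :]).ravel()
    order = np.argsort(scores)
    scores, weights = scores[order], weights[order]
    uniq, starts = np.unique(scores, return_index=True)
    mass = np.add.reduceat(weights, starts)
    sf = np.cumsum(mass[::-1])[::-1]
    ok = np.nonzero(sf <= p_cutoff)[0]
    if len(ok) == 0:
        return int(uniq[-1]), False
    return int(uniq[ok[0]]), True


def brute_window_overlap(cpgs, peaks, window=500):
    """All-pairs interval intersection; cpgs is a list of (chrom, pos_1based)."""
    hits = []
    half = window // 2
    for chrom, pos in cpgs:
        start, end = pos - 1 - half, pos - 1 + half
        hit = any(
            p.chrom == chrom and min(end, p.end) - max(start, p.start) > 0
            for p in peaks
        )
        hits.append(hit)
    return hits


def ols_oracle(x, y):
    """Closed-form simple OLS: slope, intercept, r-squared."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    xbar, ybar = x.mean(), y.mean()
    sxx = ((x - xbar) ** 2).sum()
    sxy = ((x - xbar) * (y - ybar)).sum()
    slope = sxy / sxx
    intercept = ybar - slope * xbar
    syy = ((y - ybar) ** 2).sum()
    r2 = sxy**2 / (sxx * syy) if syy > 0 else 1.0
    return slope, intercept, r2


def welch_oracle(a, b):
    """Closed-form Welch t and two-sided p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    va, vb = a.var(ddof=1) / len(a), b.var(ddof=1) / len(b)
    t = (a.mean() - b.mean()) / math.sqrt(va + vb)
    df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return t, p
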