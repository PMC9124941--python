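"""Independent brute-force oracles used only by the test suite.

Everything here is deliberately naive and, where possible, exact: integer
binomial-coefficient enumeration for the conditional 2x2 distribution, an
explicit rebuild-and-retest fragility scan, Monte-Carlo permutation tests for
the rank statistics, and sort-and-interpolate quantiles.  None of it shares
code with the package implementation.
"""

from __future__ import annotations

import math
from fractions import Fraction

import numpy as np


def hypergeom_pmf_exact(x: int, N: int, K: int, n: int) -> Fraction:
    return Fraction(math.comb(K, x) * math.comb(N - K, n - x), math.comb(N, n))


def fisher_p_exact(a: int, b: int, c: int, d: int) -> Fraction:
    """Two-sided Fisher p by full enumeration in exact integer arithmetic,
    strict minimum-likelihood rule."""
    N, K, n = a + b + c + d, a + c, a + b
    lo, hi = max(0, n + K - N), min(n, K)
    nums = [math.comb(K, x) * math.comb(N - K, n - x) for x in range(lo, hi + 1)]
    obs = nums[a - lo]
    return Fraction(sum(v for v in nums if v <= obs), math.comb(N, n))


def fragility_scan_exact(a: int, b: int, c: int, d: int, alpha: float = 0.05):
    """Naive fragility scan: explicitly rebuild each modified table and call
    the exact test.  Modifies the arm with fewer events in the original
    table; on a tie both directions are scanned and the smaller index wins.

    Returns (fi, exhausted).
    """
    if float(fisher_p_exact(a, b, c, d)) >= alpha:
        return 0, False

    def scan(ea, na, eb, nb, swap):
        # add events to arm (ea, na); swap flags which arm that is
        for k in range(1, na + 1):
            cells = (eb, nb, ea + k, na - k) if swap else (ea + k, na - k, eb, nb)
            if float(fisher_p_exact(*cells)) >= alpha:
                return k, False
        return na, True

    candidates = []
    if a <= c:
        candidates.append(scan(a, b, c, d, swap=False))
    if c <= a:
        candidates.append(scan(c, d, a, b, swap=True))
    return min(candidates, key=lambda t: (t[1], t[0]))


def midranks(values) -> np.ndarray:
    v = np.asarray(values, dtype=float)
    order = np.argsort(v, kind="mergesort")
    ranks = np.empty(v.size, dtype=float)
    i = 0
    while i < v.size:
        j = i
        while j + 1 < v.size and v[order[j + 1]] == v[order[i]]:
            j += 1
        ranks[order[i : j + 1]] = 0.5 * (i + j) + 1.0
        i = j + 1
    return ranks


def perm_p_mwu(x, y, n_perm: int, rng: np.random.Generator) -> float:
    """Two-sided permutation p for the Mann-Whitney U statistic (distance of
    U from its null mean)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    ranks = midranks(np.concatenate([x, y]))
    u_obs = ranks[:n1].sum() - n1 * (n1 + 1) / 2.0
    dev_obs = abs(u_obs - n1 * n2 / 2.0)
    idx = np.argsort(rng.random((n_perm, n1 + n2)), axis=1)[:, :n1]
    u_perm = ranks[idx].sum(axis=1) - n1 * (n1 + 1) / 2.0
    dev = np.abs(u_perm - n1 * n2 / 2.0)
    return float(np.mean(dev >= dev_obs - 1e-12))


def _kw_h(ranks: np.ndarray, sizes, tie_term: float) -> np.ndarray:
    N = ranks.shape[-1]
    h = np.zeros(ranks.shape[:-1])
    start = 0
    for n_j in sizes:
        r_j = ranks[..., start : start + n_j].sum(axis=-1)
        h = h + r_j**2 / n_j
        start += n_j
    h = 12.0 / (N * (N + 1)) * h - 3.0 * (N + 1)
    return h / tie_term


def perm_p_kw(groups, n_perm: int, rng: np.random.Generator) -> float:
    """Permutation p for the tie-corrected Kruskal-Wallis H statistic."""
    arrays = [np.asarray(g, dtype=float) for g in groups]
    sizes = [a.size for a in arrays]
    pooled = np.concatenate(arrays)
    N = pooled.size
    ranks = midranks(pooled)
    _, counts = np.unique(pooled, return_counts=True)
    tie_term = 1.0 - (counts**3 - counts).sum() / (N**3 - N)
    h_obs = float(_kw_h(ranks[None, :], sizes, tie_term)[0])
    idx = np.argsort(rng.random((n_perm, N)), axis=1)
    h_perm = _kw_h(ranks[idx], sizes, tie_term)
    return float(np.mean(h_perm >= h_obs - 1e-12))


def quantile_linear(values, p: float) -> float:
    """Sort-and-interpolate quantile at position h = (n-1)p + 1."""
    v = sorted(float(x) for x in values)
    h = (len(v) - 1) * p
    lo = math.floor(h)
    hi = min(lo + 1, len(v) - 1)
    return v[lo] + (h - lo) * (v[hi] - v[lo])


def spearman_rho_oracle(x, y) -> float:
    """Rank both variables (mid-ranks), then Pearson correlation."""
    rx, ry = midranks(x), midranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / math.sqrt((rx**2).sum() * (ry**2).sum()))
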