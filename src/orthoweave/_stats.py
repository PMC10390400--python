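"""Rank-based two-sample testing and multiple-testing helpers.

The marker and differential-expression machinery is built on the two-sided
Wilcoxon rank-sum (Mann-Whitney) test. Large groups use the normal
approximation with midrank tie correction and a 0.5 continuity correction;
when both groups have at most ``EXACT_MAX`` observations the permutation
distribution of the rank sum is enumerated exactly (midranks included), so
heavily tied small-sample comparisons stay exact.
"""

from __future__ import annotations

from itertools import combinations

import numpy as np
from scipy.stats import norm
from statsmodels.stats.multitest import multipletests

EXACT_MAX = 10


def _tie_term(sorted_cols: np.ndarray) -> np.ndarray:
    """sum(t^3 - t) over tie groups, per column of an ascending-sorted array."""
    n, g = sorted_cols.shape
    out = np.zeros(g)
    for j in range(g):
        col = sorted_cols[:, j]
        # run-length encode
        change = np.flatnonzero(col[1:] != col[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n]))
        t = ends - starts
        t = t[t > 1]
        if t.size:
            out[j] = np.sum(t**3 - t)
    return out


def _exact_two_sided_p(x: np.ndarray, y: np.ndarray) -> float:
    """Exact two-sided p by enumerating all assignments of midranks to group x."""
    pooled = np.concatenate([x, y])
    n = pooled.size
    na = x.size
    order = np.argsort(pooled, kind="mergesort")
    ranks = np.empty(n)
    sorted_vals = pooled[order]
    # midranks
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_vals[j + 1] == sorted_vals[i]:
            j += 1
        ranks[order[i : j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    observed = ranks[:na].sum()
    sums = np.array([ranks[list(c)].sum() for c in combinations(range(n), na)])
    eps = 1e-9
    p_le = np.mean(sums <= observed + eps)
    p_ge = np.mean(sums >= observed - eps)
    return min(1.0, 2.0 * min(p_le, p_ge))


def rank_sum_test(xa: np.ndarray, xb: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Wilcoxon rank-sum test, columnwise.

    Parameters
    ----------
    xa, xb
        Arrays of shape (n_a, n_genes) and (n_b, n_genes): the two groups of
        observations for each gene.

    Returns
    -------
    u : ndarray
        Mann-Whitney U statistic of group *a*, per gene.
    p : ndarray
        Two-sided p-values in (0, 1].
    """
    xa = np.atleast_2d(np.asarray(xa, dtype=float))
    xb = np.atleast_2d(np.asarray(xb, dtype=float))
    na, g = xa.shape
    nb = xb.shape[0]
    if xb.shape[1] != g:
        raise ValueError("group arrays must have the same number of genes")
    if na == 0 or nb == 0:
        raise ValueError("both groups must be non-empty")
    n = na + nb
    pooled = np.vstack([xa, xb])

    # midranks per column
    order = np.argsort(pooled, axis=0, kind="mergesort")
    ranks = np.empty_like(pooled)
    srt = np.take_along_axis(pooled, order, axis=0)
    base = np.arange(1, n + 1, dtype=float)[:, None]
    # average ranks over tie runs, column by column
    avg = np.empty_like(srt)
    for j in range(g):
        col = srt[:, j]
        change = np.flatnonzero(col[1:] != col[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [n]))
        a = np.empty(n)
        for s, e in zip(starts, ends):
            a[s:e] = (s + e - 1) / 2.0 + 1.0
        avg[:, j] = a
    np.put_along_axis(ranks, order, avg, axis=0)
    del base

    r1 = ranks[:na].sum(axis=0)
    u = r1 - na * (na + 1) / 2.0

    if na <= EXACT_MAX and nb <= EXACT_MAX:
        p = np.array([_exact_two_sided_p(xa[:, j], xb[:, j]) for j in range(g)])
        return u, p

    mu = na * nb / 2.0
    tie = _tie_term(srt)
    sigma2 = na * nb / 12.0 * ((n + 1) - tie / (n * (n - 1.0)))
    sigma = np.sqrt(sigma2)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = (np.abs(u - mu) - 0.5) / sigma
    z = np.where(sigma == 0, 0.0, np.maximum(z, 0.0))
    p = np.minimum(1.0, 2.0 * norm.sf(z))
    p = np.where(sigma == 0, 1.0, p)
    return u, np.clip(p, np.finfo(float).tiny, 1.0)


def bh_adjust(p: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (empty-safe)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multipletests(p, method="fdr_bh")[1]
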