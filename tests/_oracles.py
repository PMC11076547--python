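"""Independent brute-force oracles used across the test suite.

Everything here is deliberately naive -- direct enumeration, O(n^2)
scans, textbook formulas -- and shares no code with the package, so a
test comparing the two is a genuine cross-check.
"""

from __future__ import annotations

import math
from itertools import combinations

import numpy as np


def accumulate_sum(values) -> float:
    """Element-by-element accumulation (duration oracle)."""
    total = 0.0
    for v in values:
        total += float(v)
    return total


def maximal_runs(onsets, gap_s: float) -> list[list[int]]:
    """O(n^2) maximal-run segmentation of sorted onset indices."""
    n = len(onsets)
    runs = []
    used = set()
    for i in range(n):
        if i in used:
            continue
        run = [i]
        for j in range(i + 1, n):
            if onsets[j] - onsets[run[-1]] <= gap_s:
                run.append(j)
            else:
                break
        used.update(run)
        runs.append(run)
    return runs


def graph_components(n_nodes: int, edges) -> list[set[int]]:
    """Connected components by repeated breadth-first search."""
    adj = {i: set() for i in range(n_nodes)}
    for a, b in edges:
        adj[a].add(b)
        adj[b].add(a)
    seen: set[int] = set()
    comps = []
    for start in range(n_nodes):
        if start in seen:
            continue
        comp, frontier = {start}, [start]
        while frontier:
            node = frontier.pop()
            for nb in adj[node]:
                if nb not in comp:
                    comp.add(nb)
                    frontier.append(nb)
        seen |= comp
        comps.append(comp)
    return comps


# -- classical statistics ---------------------------------------------------


def rankdata_midrank(x) -> np.ndarray:
    """Mid-rank ranking (average rank for ties)."""
    x = np.asarray(x, dtype=float)
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    i = 0
    while i < len(x):
        j = i
        while j + 1 < len(x) and x[order[j + 1]] == x[order[i]]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def spearman_r(x, y) -> float:
    """Pearson correlation of mid-ranks (the direct rank formula)."""
    rx, ry = rankdata_midrank(x), rankdata_midrank(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float(np.sum(rx * ry) / math.sqrt(np.sum(rx ** 2) * np.sum(ry ** 2)))


def ks_statistic(a, b) -> float:
    """Max absolute ECDF gap, scanned over every pooled point."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    best = 0.0
    for t in np.concatenate([a, b]):
        fa = np.mean(a <= t)
        fb = np.mean(b <= t)
        best = max(best, abs(fa - fb))
    return float(best)


def hypergeom_pmf(a: int, row1: int, row2: int, col1: int) -> float:
    """P(top-left cell = a) given fixed margins."""
    return (math.comb(row1, a) * math.comb(row2, col1 - a)
            / math.comb(row1 + row2, col1))


def fisher_two_sided_p(table) -> float:
    """Exact two-sided p by enumerating all tables with the margins and
    summing those no more probable than the observed one."""
    (a, b), (c, d) = [[int(v) for v in row] for row in table]
    row1, row2, col1 = a + b, c + d, a + c
    p_obs = hypergeom_pmf(a, row1, row2, col1)
    lo, hi = max(0, col1 - row2), min(row1, col1)
    total = 0.0
    for k in range(lo, hi + 1):
        pk = hypergeom_pmf(k, row1, row2, col1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


def exhaustive_two_group_p(values, n_first: int, alternative: str = "less"):
    """Exact permutation p for a mean-difference statistic by enumerating
    every split of `values` into groups of size n_first / rest."""
    values = np.asarray(values, dtype=float)
    n = len(values)
    idx = set(range(n))
    obs = values[:n_first].mean() - values[list(idx - set(range(n_first)))].mean()
    stats = []
    for first in combinations(range(n), n_first):
        rest = list(idx - set(first))
        stats.append(values[list(first)].mean() - values[rest].mean())
    stats = np.asarray(stats)
    if alternative == "less":
        return float(np.mean(stats <= obs))
    if alternative == "greater":
        return float(np.mean(stats >= obs))
    centre = stats.mean()
    return float(np.mean(np.abs(stats - centre) >= abs(obs - centre)))
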