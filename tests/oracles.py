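"""Independent brute-force oracles used only by the test suite.

These deliberately avoid the library's own code paths: the
hypergeometric tail is exact rational arithmetic, traversal counts come
from explicit enumeration of every shortest path, and the pooled t is
the closed-form classical statistic.
"""

from fractions import Fraction
from math import comb

import networkx as nx
import numpy as np
from scipy import stats


def exact_hypergeom_tail(r: int, n: int, R: int, N: int) -> Fraction:
    """P(X >= r) summed exactly with rational arithmetic."""
    return sum((Fraction(comb(R, i) * comb(N - R, n - i), comb(N, n))
                for i in range(r, min(n, R) + 1)), Fraction(0))


def brute_force_traversals(graph: nx.DiGraph, pairs):
    """Interior-node traversal counts by enumerating every shortest path."""
    counts = {v: 0 for v in graph.nodes}
    n_paths = 0
    for s, t in pairs:
        if s == t or s not in graph or t not in graph:
            continue
        try:
            paths = list(nx.all_shortest_paths(graph, s, t))
        except nx.NetworkXNoPath:
            continue
        n_paths += len(paths)
        for path in paths:
            for v in path[1:-1]:
                counts[v] += 1
    return counts, n_paths


def pooled_t(x1: np.ndarray, x2: np.ndarray):
    """Classical two-sample pooled-variance t and two-sided p, per row."""
    n1, n2 = x1.shape[1], x2.shape[1]
    df = n1 + n2 - 2
    diff = x2.mean(axis=1) - x1.mean(axis=1)
    sp2 = ((n1 - 1) * x1.var(axis=1, ddof=1)
           + (n2 - 1) * x2.var(axis=1, ddof=1)) / df
    t = diff / np.sqrt(sp2 * (1 / n1 + 1 / n2))
    p = 2 * stats.t.sf(np.abs(t), df)
    return t, p


def bh_adjust(pvals):
    """Benjamini-Hochberg adjusted p-values, coded directly from the
    step-up definition (p * m / rank, then running minimum from the top)."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adj = [0.0] * m
    running = 1.0
    for pos in range(m - 1, -1, -1):
        i = order[pos]
        running = min(running, pvals[i] * m / (pos + 1))
        adj[i] = running
    return adj
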