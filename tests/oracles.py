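"""Independent brute-force / closed-form oracles used by the test suite.

These deliberately avoid the package's own code paths.
"""

import itertools
import math

import numpy as np
from scipy import stats as sp_stats


def brute_force_min_arrangement(nodes, edges):
    """Minimum linear-arrangement cost by enumerating all permutations."""
    nodes = list(nodes)
    n = len(nodes)
    index = {g: i for i, g in enumerate(nodes)}
    pairs = [(index[u], index[v]) for u, v in edges]
    perms = np.array(list(itertools.permutations(range(1, n + 1))))
    costs = np.zeros(len(perms), dtype=int)
    for i, j in pairs:
        costs += np.abs(perms[:, i] - perms[:, j])
    return int(costs.min())


def arrangement_cost(position, edges):
    return sum(abs(position[u] - position[v]) for u, v in edges)


def bh_step_up(pvals):
    """Textbook BH: p_(i) * n / i with step-up monotonisation."""
    n = len(pvals)
    order = sorted(range(n), key=lambda i: pvals[i])
    adj = [0.0] * n
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, pvals[i] * n / rank)
        adj[i] = running
    return adj


def hypergeom_upper_tail(universe, term, cluster):
    """P(overlap >= observed) by enumerating all draws of |cluster| genes."""
    universe = sorted(universe)
    term = set(term)
    k = len(cluster)
    observed = len(set(cluster) & term)
    total = 0
    hits = 0
    for draw in itertools.combinations(universe, k):
        total += 1
        if len(set(draw) & term) >= observed:
            hits += 1
    return hits / total


def pooled_t_two_group(x1, x2):
    """Ordinary two-sample pooled-variance t and two-sided p."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    n1, n2 = len(x1), len(x2)
    df = n1 + n2 - 2
    s2 = (((x1 - x1.mean()) ** 2).sum() + ((x2 - x2.mean()) ** 2).sum()) / df
    t = (x1.mean() - x2.mean()) / math.sqrt(s2 * (1 / n1 + 1 / n2))
    p = 2 * sp_stats.t.sf(abs(t), df)
    return t, p


def moderated_t_direct(x1, x2, d0, s20):
    """Closed-form moderated t for fixed prior (d0, s20), per position."""
    x1 = np.asarray(x1, float)
    x2 = np.asarray(x2, float)
    n1, n2 = x1.shape[1], x2.shape[1]
    d = n1 + n2 - 2
    s2 = (((x1 - x1.mean(1, keepdims=True)) ** 2).sum(1)
          + ((x2 - x2.mean(1, keepdims=True)) ** 2).sum(1)) / d
    if math.isinf(d0):
        s2_post = np.full_like(s2, s20)
        df_total = math.inf
    else:
        s2_post = (d0 * s20 + d * s2) / (d0 + d)
        df_total = d0 + d
    t = (x1.mean(1) - x2.mean(1)) / np.sqrt(s2_post * (1 / n1 + 1 / n2))
    p = 2 * sp_stats.t.sf(np.abs(t), df_total)
    return t, p


def window_mean_direct(matrix, radius):
    """Per-position truncated-window mean, one position at a time."""
    n = matrix.shape[0]
    out = np.empty_like(matrix, dtype=float)
    for i in range(n):
        lo = max(0, i - radius)
        hi = min(n - 1, i + radius)
        out[i] = matrix[lo:hi + 1].mean(axis=0)
    return out
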