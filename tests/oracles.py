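"""Independent brute-force oracles used by the test suite.

Everything here is deliberately naive (queue BFS, pair enumeration, ECDF
step-walking) and shares no code with the package implementations it
checks.
"""

from collections import deque

import numpy as np


def bfs_distances(adjacency: dict, start) -> dict:
    """Plain queue BFS over an adjacency-dict graph."""
    dist = {start: 0}
    queue = deque([start])
    while queue:
        node = queue.popleft()
        for nb in adjacency.get(node, ()):
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return dist


def adjacency_from_edges(edges) -> dict:
    adj: dict = {}
    for u, v in edges:
        adj.setdefault(u, set()).add(v)
        adj.setdefault(v, set()).add(u)
    return adj


def aspl_enumeration(edges, nodes=None) -> float:
    """Mean shortest-path length over connected ordered pairs, largest
    component, by running BFS from every node."""
    adj = adjacency_from_edges(edges)
    if nodes is not None:
        for n in nodes:
            adj.setdefault(n, set())
    comps = []
    seen = set()
    for n in adj:
        if n in seen:
            continue
        comp = set(bfs_distances(adj, n))
        seen |= comp
        comps.append(comp)
    comp = max(comps, key=len)
    total, count = 0, 0
    for n in comp:
        for other, d in bfs_distances(adj, n).items():
            if other != n and other in comp:
                total += d
                count += 1
    return total / count


def clustering_enumeration(edges, nodes) -> float:
    """Average local clustering by direct triangle counting."""
    adj = adjacency_from_edges(edges)
    vals = []
    for n in nodes:
        nb = sorted(adj.get(n, ()))
        k = len(nb)
        if k < 2:
            vals.append(0.0)
            continue
        links = sum(1 for i in range(k) for j in range(i + 1, k)
                    if nb[j] in adj.get(nb[i], ()))
        vals.append(2.0 * links / (k * (k - 1)))
    return float(np.mean(vals))


def ks_statistic_brute(a, b) -> float:
    """Max gap between the two empirical CDFs, walked point by point."""
    a, b = np.sort(np.asarray(a, float)), np.sort(np.asarray(b, float))
    gaps = []
    for x in np.concatenate([a, b]):
        fa = np.mean(a <= x)
        fb = np.mean(b <= x)
        gaps.append(abs(fa - fb))
    return float(max(gaps))


def ks_exact_pvalue_brute(a, b) -> float:
    """Exact two-sided p-value by enumerating all group assignments.

    Under the null every partition of the pooled sample into sizes
    (len(a), len(b)) is equally likely; the p-value is the fraction of
    partitions whose K-S statistic is >= the observed one.  Feasible for
    tiny samples only.
    """
    from itertools import combinations

    pooled = np.concatenate([a, b])
    n_a = len(a)
    observed = ks_statistic_brute(a, b)
    count, total = 0, 0
    for idx in combinations(range(len(pooled)), n_a):
        mask = np.zeros(len(pooled), dtype=bool)
        mask[list(idx)] = True
        d = ks_statistic_brute(pooled[mask], pooled[~mask])
        count += d >= observed - 1e-12
        total += 1
    return count / total
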