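"""Independent brute-force reference implementations.

Deliberately naive: triangle enumeration, BFS distance tables, recursive
shortest-path enumeration for betweenness, exhaustive set-partition search
for modularity, longhand sums of squares for the repeated-measures ANOVA.
These never share code with the package and exist only to cross-check it.
"""

from __future__ import annotations

import itertools
import math

import numpy as np


def bfs_distances(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest paths by explicit breadth-first search."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    for s in range(n):
        dist[s, s] = 0
        frontier = [s]
        d = 0
        seen = {s}
        while frontier:
            d += 1
            nxt = []
            for u in frontier:
                for v in range(n):
                    if adj[u, v] and v not in seen:
                        seen.add(v)
                        dist[s, v] = d
                        nxt.append(v)
            frontier = nxt
    return dist


def clustering_per_node(adj: np.ndarray) -> np.ndarray:
    """Triangle density among each node's neighbours, by enumeration."""
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        k = len(nbrs)
        if k < 2:
            continue
        links = sum(
            1 for a, b in itertools.combinations(nbrs, 2) if adj[a, b]
        )
        out[i] = 2 * links / (k * (k - 1))
    return out


def characteristic_path_length(adj: np.ndarray) -> float:
    d = bfs_distances(adj)
    n = adj.shape[0]
    vals = [d[i, j] for i in range(n) for j in range(n) if i != j and math.isfinite(d[i, j])]
    return float(np.mean(vals)) if vals else float("nan")


def global_efficiency(adj: np.ndarray) -> float:
    d = bfs_distances(adj)
    n = adj.shape[0]
    if n < 2:
        return float("nan")
    tot = sum(
        1.0 / d[i, j]
        for i in range(n)
        for j in range(n)
        if i != j and math.isfinite(d[i, j]) and d[i, j] > 0
    )
    return tot / (n * (n - 1))


def nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    d = bfs_distances(adj)
    n = adj.shape[0]
    out = np.zeros(n)
    for i in range(n):
        out[i] = sum(
            1.0 / d[i, j] for j in range(n) if j != i and math.isfinite(d[i, j])
        ) / (n - 1)
    return out


def local_efficiency(adj: np.ndarray) -> float:
    n = adj.shape[0]
    vals = []
    for i in range(n):
        nbrs = [j for j in range(n) if adj[i, j]]
        if len(nbrs) < 2:
            vals.append(0.0)
            continue
        sub = adj[np.ix_(nbrs, nbrs)]
        vals.append(global_efficiency(sub))
    return float(np.mean(vals))


def _count_shortest_paths(adj, s, t, dist):
    """All shortest s→t paths as node tuples, by recursive descent."""
    if s == t:
        return [(s,)]
    paths = []
    for u in range(adj.shape[0]):
        if adj[t, u] and dist[s, u] == dist[s, t] - 1:
            for p in _count_shortest_paths(adj, s, u, dist):
                paths.append(p + (t,))
    return paths


def betweenness(adj: np.ndarray) -> np.ndarray:
    """Fractional shortest-path betweenness by full path enumeration,
    normalised by (N−1)(N−2)/2. Only usable for small n."""
    n = adj.shape[0]
    dist = bfs_distances(adj)
    score = np.zeros(n)
    for s in range(n):
        for t in range(s + 1, n):
            if not math.isfinite(dist[s, t]):
                continue
            paths = _count_shortest_paths(adj, s, t, dist)
            for p in paths:
                for v in p[1:-1]:
                    score[v] += 1.0 / len(paths)
    norm = (n - 1) * (n - 2) / 2
    return score / norm if norm > 0 else score


def modularity_of_labels(adj: np.ndarray, labels) -> float:
    """Q = Σ_m [e_mm − a_m²] computed longhand from the definition."""
    labels = np.asarray(labels)
    two_m = adj.sum()
    if two_m == 0:
        return float("nan")
    q = 0.0
    for lab in np.unique(labels):
        idx = np.flatnonzero(labels == lab)
        e_mm = adj[np.ix_(idx, idx)].sum() / two_m
        a_m = adj[idx, :].sum() / two_m
        q += e_mm - a_m * a_m
    return q


def _set_partitions(n: int):
    """All set partitions of range(n) via restricted growth strings."""
    a = [0] * n
    b = [0] * n  # b[i] = max(a[:i+1])

    def rec(i):
        if i == n:
            yield tuple(a)
            return
        for v in range(b[i - 1] + 2 if i else 1):
            a[i] = v
            if i + 1 < n:
                b[i] = max(b[i - 1], v) if i else v
            yield from rec(i + 1)

    yield from rec(0)


def best_modularity_exhaustive(adj: np.ndarray) -> tuple[float, tuple]:
    """The global optimum of Q over every partition (n ≤ 8 feasible)."""
    best_q, best_p = -np.inf, None
    for p in _set_partitions(adj.shape[0]):
        q = modularity_of_labels(adj, p)
        if q > best_q:
            best_q, best_p = q, p
    return best_q, best_p


def loglog_slope(k: np.ndarray, c: np.ndarray) -> tuple[float, float]:
    """Least-squares slope and R² of log c on log k, longhand."""
    x, y = np.log(np.asarray(k, float)), np.log(np.asarray(c, float))
    xm, ym = x.mean(), y.mean()
    slope = ((x - xm) * (y - ym)).sum() / ((x - xm) ** 2).sum()
    inter = ym - slope * xm
    ss_res = ((y - slope * x - inter) ** 2).sum()
    ss_tot = ((y - ym) ** 2).sum()
    return slope, 1 - ss_res / ss_tot if ss_tot > 0 else 1.0


def pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    xm, ym = x - x.mean(), y - y.mean()
    return float((xm * ym).sum() / np.sqrt((xm**2).sum() * (ym**2).sum()))


def rm_anova_longhand(table: np.ndarray) -> tuple[float, tuple[float, float]]:
    """One-way repeated-measures F via textbook sums of squares."""
    n, k = table.shape
    grand = table.mean()
    ss_between_cond = n * sum((table[:, j].mean() - grand) ** 2 for j in range(k))
    ss_between_subj = k * sum((table[i, :].mean() - grand) ** 2 for i in range(n))
    ss_total = ((table - grand) ** 2).sum()
    ss_error = ss_total - ss_between_cond - ss_between_subj
    df1, df2 = k - 1, (k - 1) * (n - 1)
    return (ss_between_cond / df1) / (ss_error / df2), (df1, df2)


def trapezoid(y: np.ndarray, x: np.ndarray) -> float:
    """Trapezoidal rule, summed pairwise."""
    total = 0.0
    for i in range(len(x) - 1):
        total += 0.5 * (y[i] + y[i + 1]) * (x[i + 1] - x[i])
    return total
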