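"""Independent brute-force oracles used by the test suite.

Deliberately naive implementations: shortest paths by explicit enumeration,
partial correlation by ordinary least squares on ranks, Mann-Whitney by
exhaustive rank-assignment enumeration, modularity maximization by exhaustive
search over all set partitions. They share no code with the package paths
they check.
"""

from __future__ import annotations

from itertools import combinations, permutations

import numpy as np
from scipy import stats


def all_shortest_paths(adj: np.ndarray, s: int, t: int) -> list[tuple[int, ...]]:
    """Every shortest s-t path: BFS distances, then walk the distance DAG."""
    if s == t:
        return [(s,)]
    dist = {s: 0}
    frontier = [s]
    while frontier:
        nxt = []
        for v in frontier:
            for w in np.nonzero(adj[v])[0]:
                w = int(w)
                if w not in dist:
                    dist[w] = dist[v] + 1
                    nxt.append(w)
        frontier = nxt
    if t not in dist:
        return []
    paths: list[tuple[int, ...]] = []

    def extend(path: list[int]) -> None:
        v = path[-1]
        if v == t:
            paths.append(tuple(path))
            return
        if dist[v] >= dist[t]:
            return
        for w in np.nonzero(adj[v])[0]:
            w = int(w)
            if dist.get(w) == dist[v] + 1:
                extend(path + [w])

    extend([s])
    return paths


def betweenness_oracle(adj: np.ndarray) -> np.ndarray:
    """Unnormalized betweenness over unordered pairs by path enumeration."""
    n = adj.shape[0]
    bc = np.zeros(n)
    for s, t in combinations(range(n), 2):
        paths = all_shortest_paths(adj, s, t)
        if not paths:
            continue
        for v in range(n):
            if v in (s, t):
                continue
            through = sum(1 for p in paths if v in p[1:-1])
            bc[v] += through / len(paths)
    return bc


def distances_oracle(adj: np.ndarray) -> np.ndarray:
    """All-pairs shortest-path lengths by repeated single-pair enumeration."""
    n = adj.shape[0]
    dist = np.full((n, n), np.inf)
    np.fill_diagonal(dist, 0)
    for s, t in combinations(range(n), 2):
        paths = all_shortest_paths(adj, s, t)
        if paths:
            dist[s, t] = dist[t, s] = len(paths[0]) - 1
    return dist


def global_efficiency_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    dist = distances_oracle(adj)
    with np.errstate(divide="ignore"):
        inv = 1.0 / dist
    np.fill_diagonal(inv, 0.0)
    return inv.sum(axis=1) / (n - 1)


def local_efficiency_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = np.nonzero(adj[v])[0]
        if len(nb) < 2:
            continue
        sub = adj[np.ix_(nb, nb)]
        out[v] = global_efficiency_oracle(sub).mean()
    return out


def clustering_oracle(adj: np.ndarray) -> np.ndarray:
    n = adj.shape[0]
    out = np.zeros(n)
    for v in range(n):
        nb = np.nonzero(adj[v])[0]
        k = len(nb)
        if k < 2:
            continue
        connected_pairs = sum(
            1 for a, b in combinations(nb, 2) if adj[a, b]
        )
        out[v] = connected_pairs / (k * (k - 1) / 2)
    return out


def partial_spearman_oracle(
    x: np.ndarray, y: np.ndarray, covariates: np.ndarray | None
) -> float:
    """Rank everything, regress each rank vector on [1, ranked covariates]
    by explicit normal equations, correlate the residuals."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    if covariates is None:
        design = np.ones((n, 1))
    else:
        cov = np.atleast_2d(np.asarray(covariates, float))
        if cov.shape[0] != n:
            cov = cov.T
        design = np.column_stack(
            [np.ones(n)] + [stats.rankdata(cov[:, j]) for j in range(cov.shape[1])]
        )
    beta_x = np.linalg.solve(design.T @ design, design.T @ rx)
    beta_y = np.linalg.solve(design.T @ design, design.T @ ry)
    ex = rx - design @ beta_x
    ey = ry - design @ beta_y
    return float(stats.pearsonr(ex, ey)[0])


def mann_whitney_exact_oracle(a: np.ndarray, b: np.ndarray) -> tuple[float, float]:
    """U statistic and exact two-sided p by enumerating all rank assignments.

    Valid for untied samples; enumerates every C(n_a + n_b, n_a) split of the
    pooled sample.
    """
    a, b = np.asarray(a, float), np.asarray(b, float)
    n_a, n_b = len(a), len(b)
    pooled = np.concatenate([a, b])
    assert len(np.unique(pooled)) == len(pooled), "oracle requires no ties"
    ranks = stats.rankdata(pooled)
    u_a = float(ranks[:n_a].sum() - n_a * (n_a + 1) / 2)

    def u_of(idx: tuple[int, ...]) -> float:
        return float(sum(ranks[list(idx)]) - n_a * (n_a + 1) / 2)

    us = [u_of(idx) for idx in combinations(range(n_a + n_b), n_a)]
    us = np.asarray(us)
    mean_u = n_a * n_b / 2
    extreme = np.sum(np.abs(us - mean_u) >= abs(u_a - mean_u) - 1e-12)
    return max(u_a, n_a * n_b - u_a), float(extreme / len(us))


def modularity_oracle(adj: np.ndarray, labels: np.ndarray) -> float:
    two_m = adj.sum()
    if two_m == 0:
        return 0.0
    k = adj.sum(axis=1)
    b = adj - np.outer(k, k) / two_m
    same = np.asarray(labels)[:, None] == np.asarray(labels)[None, :]
    return float((b * same).sum() / two_m)


def max_modularity_oracle(adj: np.ndarray) -> float:
    """Exhaustive search over all set partitions of the nodes."""
    from sympy.utilities.iterables import multiset_partitions

    two_m = adj.sum()
    if two_m == 0:
        return 0.0
    k = adj.sum(axis=1)
    b = adj - np.outer(k, k) / two_m
    n = adj.shape[0]
    best = -np.inf
    for part in multiset_partitions(list(range(n))):
        q = sum(b[np.ix_(blk, blk)].sum() for blk in part)
        if q > best:
            best = q
    return float(best / two_m)


def random_binary_graph(
    rng: np.random.Generator, n: int, p: float
) -> np.ndarray:
    a = (rng.random((n, n)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T
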