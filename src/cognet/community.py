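"""Louvain community detection and Newman modularity, from first principles.

Modularity of a partition on a (possibly weighted) undirected graph:

    Q = (1/2m) * sum_ij [A_ij - gamma * k_i k_j / (2m)] * delta(c_i, c_j)

with k the (weighted) degrees, 2m the total weight, and gamma the resolution
(1 by default). The Louvain algorithm greedily optimizes Q in two phases —
local node moves to the best neighboring community until no move improves Q,
then aggregation of communities into super-nodes — repeated until the
partition stabilizes. Node sweep order is shuffled by the seed; with
``restarts > 1`` the best-Q partition over independent seeded runs is kept.

An edgeless graph yields the all-singleton partition with Q defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from cognet.graph import CognitiveGraph

_GAIN_EPS = 1e-12


@dataclass(frozen=True)
class Partition:
    """Node -> community mapping with its modularity score."""

    mapping: Mapping[str, int]
    modularity_Q: float

    @property
    def n_communities(self) -> int:
        return len(set(self.mapping.values()))

    def communities(self) -> list[frozenset[str]]:
        """Communities as frozensets of node labels (order by community id)."""
        by_id: dict[int, set[str]] = {}
        for node, cid in self.mapping.items():
            by_id.setdefault(cid, set()).add(node)
        return [frozenset(by_id[c]) for c in sorted(by_id)]

    def labels(self, nodes: Sequence[str]) -> np.ndarray:
        return np.asarray([self.mapping[n] for n in nodes], dtype=int)


def modularity(
    graph: Union[CognitiveGraph, np.ndarray],
    communities: Sequence[int] | Mapping[str, int],
    resolution: float = 1.0,
) -> float:
    """Newman modularity Q of a community assignment (0 on edgeless graphs)."""
    if isinstance(graph, CognitiveGraph):
        adj = np.asarray(graph.adjacency, dtype=float)
        if isinstance(communities, Mapping):
            communities = [communities[n] for n in graph.nodes]
    else:
        adj = np.asarray(graph, dtype=float)
        if isinstance(communities, Mapping):
            raise TypeError("mapping assignment needs a CognitiveGraph")
    labels = np.asarray(communities)
    if len(labels) != adj.shape[0]:
        raise ValueError("one community per node required")
    two_m = adj.sum()
    if two_m == 0:
        return 0.0
    k = adj.sum(axis=1)
    same = labels[:, None] == labels[None, :]
    return float(
        np.sum((adj - resolution * np.outer(k, k) / two_m) * same) / two_m
    )


def _one_level(
    weights: np.ndarray, rng: np.random.Generator, resolution: float
) -> np.ndarray:
    """One Louvain local-move phase; returns the community label per node.

    Convention: ``weights`` is symmetric and its diagonal carries twice the
    internal weight of an aggregated node, so row sums are degrees and the
    total sum is 2m.
    """
    n = weights.shape[0]
    two_m = weights.sum()
    k = weights.sum(axis=1)
    labels = np.arange(n)
    sigma_tot = k.copy()  # total degree per community

    improved = True
    while improved:
        improved = False
        for i in rng.permutation(n):
            a = labels[i]
            # degree of i into each community, excluding i itself
            k_in = np.zeros(n)
            for j in np.nonzero(weights[i])[0]:
                if j != i:
                    k_in[labels[j]] += weights[i, j]
            sigma_tot[a] -= k[i]
            # gain of joining community c relative to staying isolated
            candidates = np.nonzero(k_in)[0]
            best_c, best_gain = a, k_in[a] - resolution * k[i] * sigma_tot[a] / two_m
            for c in candidates:
                gain = k_in[c] - resolution * k[i] * sigma_tot[c] / two_m
                if gain > best_gain + _GAIN_EPS:
                    best_c, best_gain = c, gain
            sigma_tot[best_c] += k[i]
            if best_c != a:
                labels[i] = best_c
                improved = True
    return labels


def _aggregate(weights: np.ndarray, compact: np.ndarray) -> np.ndarray:
    """Collapse communities (compact 0..m-1 labels) into super-nodes."""
    m = int(compact.max()) + 1
    agg = np.zeros((m, m))
    for i in range(weights.shape[0]):
        for j in range(weights.shape[0]):
            agg[compact[i], compact[j]] += weights[i, j]
    return agg


def louvain(
    graph: CognitiveGraph,
    seed: int = 0,
    resolution: float = 1.0,
    restarts: int = 1,
) -> Partition:
    """Louvain partition of a binary undirected graph.

    Seeded and run once by default; ``restarts`` independent runs keep the
    best-Q result. Isolated nodes end as singleton communities. The reported
    Q is recomputed from the final mapping with :func:`modularity`, so it is
    independently checkable.
    """
    if restarts < 1:
        raise ValueError("restarts must be >= 1")
    adj = np.asarray(graph.adjacency, dtype=float)
    n = adj.shape[0]
    if adj.sum() == 0:
        return Partition(
            mapping={node: i for i, node in enumerate(graph.nodes)},
            modularity_Q=0.0,
        )

    best_labels, best_q = None, -np.inf
    streams = np.random.SeedSequence(seed).spawn(restarts)
    for stream in streams:
        rng = np.random.default_rng(stream)
        weights = adj.copy()
        assignment = np.arange(n)  # original node -> current super-node
        while True:
            labels = _one_level(weights, rng, resolution)
            uniq, compact = np.unique(labels, return_inverse=True)
            if len(uniq) == weights.shape[0]:
                break  # no merge happened; the partition is stable
            assignment = compact[assignment]
            weights = _aggregate(weights, compact)
        q = modularity(adj, assignment, resolution=resolution)
        if q > best_q:
            best_labels, best_q = assignment, q

    # compact, deterministic community ids (by first appearance in node order)
    remap: dict[int, int] = {}
    final = []
    for c in best_labels:
        if c not in remap:
            remap[c] = len(remap)
        final.append(remap[c])
    return Partition(
        mapping={node: final[i] for i, node in enumerate(graph.nodes)},
        modularity_Q=float(best_q),
    )
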