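"""Node-level graph-theory metrics on binary undirected graphs.

All metrics are implemented directly from their definitions on the adjacency
matrix (breadth-first search for shortest paths, Brandes accumulation for
betweenness) rather than delegated to a graph library, so each admits an
independent brute-force oracle:

* betweenness centrality — for node v, the sum over unordered node pairs
  {s, t} (s, t != v) of the fraction of shortest s-t paths passing through v;
  left unnormalized, matching the verbal definition and the reference
  connectivity-toolbox convention.
* clustering coefficient — fraction of a node's neighbor pairs that are
  themselves connected; 0 for degree < 2.
* global efficiency (nodal) — mean inverse shortest-path length from v to
  every other node, unreachable pairs contributing 0.
* local efficiency — whole-network global efficiency of the subgraph induced
  by v's neighbors (v excluded); 0 for degree < 2.
* connection density — degree/(N-1) per node; 2|E|/(N(N-1)) network-wide.
* hubs — nodes whose betweenness exceeds the graph mean by more than 1.5
  sample standard deviations.
"""

from __future__ import annotations

from collections import deque
from typing import Sequence

import numpy as np
import pandas as pd

from cognet.community import louvain
from cognet.graph import CognitiveGraph

#: the metric columns of a node-metric table, in output order
METRIC_COLUMNS = (
    "degree",
    "betweenness",
    "clustering",
    "local_efficiency",
    "global_efficiency",
    "density",
)

#: A node-metric table: one row per node, metric columns plus community and
#: hub assignments. (pandas DataFrame indexed by node label.)
NodeMetricSet = pd.DataFrame

HUB_SD_FACTOR = 1.5


def _as_adjacency(graph: CognitiveGraph | np.ndarray) -> np.ndarray:
    if isinstance(graph, CognitiveGraph):
        return np.asarray(graph.adjacency, dtype=np.int64)
    return np.asarray(graph, dtype=np.int64)


def _bfs_distances(adj: np.ndarray, source: int) -> np.ndarray:
    n = adj.shape[0]
    dist = np.full(n, -1, dtype=np.int64)
    dist[source] = 0
    queue = deque([source])
    while queue:
        v = queue.popleft()
        for w in np.nonzero(adj[v])[0]:
            if dist[w] < 0:
                dist[w] = dist[v] + 1
                queue.append(w)
    return dist


def betweenness(graph: CognitiveGraph | np.ndarray) -> np.ndarray:
    """Unnormalized betweenness centrality over unordered node pairs.

    Brandes' dependency accumulation: one BFS per source computes shortest-
    path counts sigma and the accumulated pair dependencies; summing over
    ordered pairs and halving gives the unordered-pair convention.
    """
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    bc = np.zeros(n, dtype=float)
    neighbors = [np.nonzero(adj[v])[0] for v in range(n)]
    for s in range(n):
        sigma = np.zeros(n)
        sigma[s] = 1.0
        dist = np.full(n, -1, dtype=np.int64)
        dist[s] = 0
        preds: list[list[int]] = [[] for _ in range(n)]
        order: list[int] = []
        queue = deque([s])
        while queue:
            v = queue.popleft()
            order.append(v)
            for w in neighbors[v]:
                if dist[w] < 0:
                    dist[w] = dist[v] + 1
                    queue.append(w)
                if dist[w] == dist[v] + 1:
                    sigma[w] += sigma[v]
                    preds[w].append(v)
        delta = np.zeros(n)
        for w in reversed(order):
            for v in preds[w]:
                delta[v] += sigma[v] / sigma[w] * (1.0 + delta[w])
            if w != s:
                bc[w] += delta[w]
    return bc / 2.0


def clustering_coefficient(graph: CognitiveGraph | np.ndarray) -> np.ndarray:
    """C(v) = 2 e_N(v) / (k_v (k_v - 1)); 0 when the degree is below 2."""
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    out = np.zeros(n, dtype=float)
    for v in range(n):
        nb = np.nonzero(adj[v])[0]
        k = len(nb)
        if k < 2:
            continue
        e_neighbors = adj[np.ix_(nb, nb)].sum() / 2.0
        out[v] = 2.0 * e_neighbors / (k * (k - 1))
    return out


def _nodal_efficiency(adj: np.ndarray) -> np.ndarray:
    """Per-node mean inverse shortest-path length (0 for unreachable)."""
    n = adj.shape[0]
    if n < 2:
        return np.zeros(n, dtype=float)
    eff = np.zeros(n, dtype=float)
    for v in range(n):
        dist = _bfs_distances(adj, v)
        reach = dist > 0
        eff[v] = np.sum(1.0 / dist[reach]) / (n - 1)
    return eff


def global_efficiency_node(graph: CognitiveGraph | np.ndarray) -> np.ndarray:
    """E_glob(v): inverse average path length from v to every other node."""
    adj = _as_adjacency(graph)
    if adj.shape[0] < 2:
        raise ValueError("global efficiency needs at least 2 nodes")
    return _nodal_efficiency(adj)


def global_efficiency(graph: CognitiveGraph | np.ndarray) -> float:
    """Whole-network global efficiency: mean of the nodal values."""
    return float(np.mean(global_efficiency_node(graph)))


def local_efficiency(graph: CognitiveGraph | np.ndarray) -> np.ndarray:
    """E_loc(v): global efficiency of the neighbor-induced subgraph of v."""
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    out = np.zeros(n, dtype=float)
    for v in range(n):
        nb = np.nonzero(adj[v])[0]
        if len(nb) < 2:
            continue
        out[v] = float(np.mean(_nodal_efficiency(adj[np.ix_(nb, nb)])))
    return out


def node_density(graph: CognitiveGraph | np.ndarray) -> np.ndarray:
    """Per-node connection density: degree / (N - 1)."""
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return adj.sum(axis=1) / (n - 1)


def whole_density(graph: CognitiveGraph | np.ndarray) -> float:
    """Whole-network connection density: 2|E| / (N(N-1))."""
    adj = _as_adjacency(graph)
    n = adj.shape[0]
    if n < 2:
        raise ValueError("density needs at least 2 nodes")
    return float(adj.sum() / (n * (n - 1)))


def hubs(bc: Sequence[float], sd_factor: float = HUB_SD_FACTOR) -> np.ndarray:
    """Boolean hub flags: betweenness > mean + sd_factor * sample SD.

    With zero spread (all betweenness equal) no node is a hub.
    """
    bc = np.asarray(bc, dtype=float)
    if len(bc) < 2:
        raise ValueError("hub detection needs at least 2 nodes")
    sd = float(np.std(bc, ddof=1))
    if sd == 0.0:
        return np.zeros(len(bc), dtype=bool)
    return bc > bc.mean() + sd_factor * sd


def node_metrics(
    graph: CognitiveGraph,
    seed: int = 0,
    resolution: float = 1.0,
    louvain_restarts: int = 1,
) -> pd.DataFrame:
    """Full node-metric table for one group graph.

    Returns a DataFrame indexed by test label with the metric columns,
    the Louvain community id of each node, and the hub flag.
    """
    bc = betweenness(graph)
    part = louvain(
        graph, seed=seed, resolution=resolution, restarts=louvain_restarts
    )
    frame = pd.DataFrame(
        {
            "degree": graph.degrees(),
            "betweenness": bc,
            "clustering": clustering_coefficient(graph),
            "local_efficiency": local_efficiency(graph),
            "global_efficiency": global_efficiency_node(graph),
            "density": node_density(graph),
            "community": [part.mapping[n] for n in graph.nodes],
            "hub": hubs(bc),
        },
        index=pd.Index(graph.nodes, name="node"),
    )
    return frame
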