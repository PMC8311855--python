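"""The binary undirected cognitive graph and its interchange formats.

Nodes are cognitive tests; an edge records a significant positive partial
correlation between two tests within a group. The adjacency matrix is the
interchange format between pipeline stages (square 0/1 CSV with test labels
as header row and column); edge-list and GraphML exports feed external
layout tools.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterator, Mapping

import networkx as nx
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class CognitiveGraph:
    """Binary undirected graph over an ordered set of test labels."""

    nodes: tuple[str, ...]
    adjacency: np.ndarray
    provenance: Mapping[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        adj = np.asarray(self.adjacency)
        n = len(self.nodes)
        if adj.shape != (n, n):
            raise ValueError(f"adjacency shape {adj.shape} != ({n}, {n})")
        if not np.array_equal(adj, adj.T):
            raise ValueError("adjacency must be symmetric")
        if not np.isin(adj, (0, 1)).all():
            raise ValueError("adjacency must be binary")
        if np.diag(adj).any():
            raise ValueError("self-loops are not allowed")
        if len(set(self.nodes)) != n:
            raise ValueError("node labels must be unique")
        object.__setattr__(self, "adjacency", adj.astype(np.int8))

    # ------------------------------------------------------------ queries

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.sum()) // 2

    def degrees(self) -> np.ndarray:
        return self.adjacency.sum(axis=1).astype(int)

    def edges(self) -> Iterator[tuple[str, str]]:
        ii, jj = np.nonzero(np.triu(self.adjacency, k=1))
        for i, j in zip(ii, jj):
            yield self.nodes[i], self.nodes[j]

    def index(self, node: str) -> int:
        return self.nodes.index(node)

    # ---------------------------------------------------------------- I/O

    def to_networkx(self) -> nx.Graph:
        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        g.add_edges_from(self.edges())
        return g

    def to_adjacency_csv(self, path: str | Path) -> None:
        frame = pd.DataFrame(
            self.adjacency, index=list(self.nodes), columns=list(self.nodes)
        )
        frame.to_csv(path)

    @classmethod
    def from_adjacency_csv(
        cls, path: str | Path, provenance: Mapping[str, object] | None = None
    ) -> "CognitiveGraph":
        frame = pd.read_csv(path, index_col=0)
        if list(frame.index) != list(frame.columns):
            raise ValueError("adjacency CSV row and column labels differ")
        return cls(
            nodes=tuple(str(c) for c in frame.columns),
            adjacency=frame.to_numpy(),
            provenance=dict(provenance or {}),
        )

    def to_edge_list(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("source\ttarget\n")
            for a, b in self.edges():
                fh.write(f"{a}\t{b}\n")

    def to_graphml(
        self,
        path: str | Path,
        node_attrs: Mapping[str, Mapping[str, object]] | None = None,
    ) -> None:
        """GraphML export (Gephi-consumable), optionally with node attributes
        such as community id, betweenness, or hub flags."""
        g = self.to_networkx()
        for attr, values in (node_attrs or {}).items():
            nx.set_node_attributes(g, dict(values), attr)
        nx.write_graphml(g, path)
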