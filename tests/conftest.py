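"""Shared fixtures: worked-example graphs and small synthetic cohorts."""

from __future__ import annotations

import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from cognet.battery import TestBattery, TestSpec, canonical_battery
from cognet.graph import CognitiveGraph
from cognet.synth import GroupSpec, SyntheticConfig, generate_cohort


def graph_from_edges(n: int, edges: list[tuple[int, int]]) -> CognitiveGraph:
    adj = np.zeros((n, n), dtype=int)
    for a, b in edges:
        adj[a, b] = adj[b, a] = 1
    return CognitiveGraph(tuple(f"n{i}" for i in range(n)), adj)


@pytest.fixture(scope="session")
def battery() -> TestBattery:
    return canonical_battery()


@pytest.fixture
def star_graph() -> CognitiveGraph:
    """Center node 0 with four mutually unconnected leaves."""
    return graph_from_edges(5, [(0, 1), (0, 2), (0, 3), (0, 4)])


@pytest.fixture
def path_graph() -> CognitiveGraph:
    """Path a-b-c-d."""
    return graph_from_edges(4, [(0, 1), (1, 2), (2, 3)])


def neighbor_example_graph(connected_pairs: int) -> CognitiveGraph:
    """The worked clustering example: a focal node with three neighbors of
    which 0, 1 or 3 pairs are connected to each other."""
    edges = [(0, 1), (0, 2), (0, 3)]
    extra = [(1, 2), (2, 3), (1, 3)]
    assert connected_pairs in (0, 1, 3)
    return graph_from_edges(4, edges + extra[:connected_pairs])


def four_block_battery() -> TestBattery:
    """16 tests in four disjoint planted domains of four tests each."""
    from cognet.battery import block_battery

    return block_battery(4)


def single_group_cohort(
    seed: int,
    n: int = 70,
    r_within: float = 0.0,
    r_between: float = 0.0,
    battery: TestBattery | None = None,
    transform: str = "none",
    covariate_effects: dict | None = None,
):
    """One-group synthetic table, defaulting to the canonical battery."""
    bat = battery or canonical_battery()
    config = SyntheticConfig(
        groups=(
            GroupSpec(
                name="g",
                n=n,
                r_within=r_within,
                r_between=r_between,
                covariate_effects=covariate_effects or {},
                age_range=(40, 70),
                education_range=(8, 18),
                marginal_transform=transform,
            ),
        ),
        seed=seed,
        battery=bat,
    )
    return generate_cohort(config)
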