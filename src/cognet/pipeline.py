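"""End-to-end orchestration: cohort -> z-scores -> graphs -> metrics -> stats.

``run_pipeline`` composes the stages for every group of a cohort and writes a
reproducible report bundle: per group the edge statistics, the 0/1 adjacency
CSV (the interchange format between stages), an edge list and GraphML export
for external layout tools, the node-metric table, the community partition and
the domain profiles; across groups the Mann-Whitney comparison table and the
whole-cohort domain-consistency table. A run manifest records every seed,
threshold and option, so a rerun with the same config yields an identical
bundle.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from itertools import combinations
from pathlib import Path
from typing import Mapping, Optional, Sequence

import pandas as pd
import yaml

from cognet.battery import TestBattery, canonical_battery
from cognet.compare import comparisons_frame, mann_whitney_metrics
from cognet.domains import (
    consistency_frame,
    domain_consistency,
    domain_means,
    domain_profiles_frame,
)
from cognet.graph import CognitiveGraph
from cognet.metrics import METRIC_COLUMNS, node_metrics
from cognet.netbuild import (
    DEFAULT_COVARIATES,
    DEFAULT_VALIDATE_BAND,
    build_edge_stats,
    threshold_to_graph,
    write_edge_stats,
)
from cognet.standardize import standardize_groups
from cognet.synth import default_config, generate_cohort
from cognet.table import group_table, read_score_table

logger = logging.getLogger(__name__)

_VERSION = "0.1.0"

DEFAULT_COMPARISON_METRICS = (
    "betweenness",
    "clustering",
    "local_efficiency",
    "global_efficiency",
    "density",
)


@dataclass(frozen=True)
class PipelineConfig:
    """Everything a full run needs; serializable as a flat key-value file."""

    cohort_path: Optional[str] = None  # None -> synthetic default cohort
    battery_path: Optional[str] = None  # None -> canonical 16-test battery
    seed: int = 0
    norm_source: str = "own-group"
    healthy_groups: tuple[str, ...] = ("young", "middle", "older")
    matched_controls: Mapping[str, str] = field(
        default_factory=lambda: {
            "amci": "older",
            "namci": "older",
            "dementia": "older",
        }
    )
    alpha: float = 0.05
    covariates: tuple[str, ...] = DEFAULT_COVARIATES
    validate_band: Optional[tuple[float, float]] = DEFAULT_VALIDATE_BAND
    n_perm: int = 5000
    drop_negative: bool = True
    use_permutation_in_band: bool = False
    louvain_restarts: int = 1
    resolution: float = 1.0
    comparison_metrics: tuple[str, ...] = DEFAULT_COMPARISON_METRICS
    comparison_pairs: Optional[tuple[tuple[str, str], ...]] = None

    def __post_init__(self) -> None:
        if not 0.0 < self.alpha < 1.0:
            raise ValueError(f"alpha must be in (0, 1), got {self.alpha}")
        unknown = set(self.comparison_metrics) - set(METRIC_COLUMNS)
        if unknown:
            raise ValueError(f"unknown comparison metrics: {sorted(unknown)}")

    def to_yaml(self, path: str | Path) -> None:
        doc = asdict(self)
        doc["matched_controls"] = dict(self.matched_controls)
        doc["validate_band"] = (
            list(self.validate_band) if self.validate_band else None
        )
        doc["comparison_pairs"] = (
            [list(p) for p in self.comparison_pairs]
            if self.comparison_pairs
            else None
        )
        with open(path, "w") as fh:
            yaml.safe_dump(doc, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        for key in ("healthy_groups", "covariates", "comparison_metrics"):
            if key in doc and doc[key] is not None:
                doc[key] = tuple(doc[key])
        if doc.get("validate_band") is not None:
            doc["validate_band"] = tuple(doc["validate_band"])
        if doc.get("comparison_pairs") is not None:
            doc["comparison_pairs"] = tuple(
                tuple(p) for p in doc["comparison_pairs"]
            )
        return cls(**doc)


def run_pipeline(
    config: PipelineConfig, out_dir: str | Path
) -> dict[str, object]:
    """Run the full analysis and write the report bundle under *out_dir*.

    Returns a dict with the in-memory artifacts: the standardized cohort,
    per-group graphs, metric tables and domain profiles, the comparison
    table and the consistency table.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    battery = (
        TestBattery.from_csv(config.battery_path)
        if config.battery_path
        else canonical_battery()
    )
    if config.cohort_path:
        cohort = read_score_table(config.cohort_path)
    else:
        cohort = generate_cohort(default_config(config.seed))

    groups = list(dict.fromkeys(cohort["group"]))
    scored = standardize_groups(
        cohort,
        battery,
        norm_source=config.norm_source,
        healthy_groups=tuple(
            g for g in config.healthy_groups if g in set(groups)
        ),
        matched_controls=config.matched_controls,
    )
    scored.to_csv(out / "cohort_zscores.csv", index=False)

    graphs: dict[str, CognitiveGraph] = {}
    metric_tables: dict[str, pd.DataFrame] = {}
    profile_rows = []
    for idx, name in enumerate(groups):
        sub = group_table(scored, name)
        edges = build_edge_stats(
            sub,
            covariates=config.covariates,
            validate_band=config.validate_band,
            n_perm=config.n_perm,
            seed=config.seed + idx,
        )
        graph = threshold_to_graph(
            edges,
            alpha=config.alpha,
            drop_negative=config.drop_negative,
            use_permutation_in_band=config.use_permutation_in_band,
            group=name,
        )
        metrics = node_metrics(
            graph,
            seed=config.seed + idx,
            resolution=config.resolution,
            louvain_restarts=config.louvain_restarts,
        )
        write_edge_stats(edges, out / f"{name}_edges.csv")
        graph.to_adjacency_csv(out / f"{name}_adjacency.csv")
        graph.to_edge_list(out / f"{name}_edgelist.tsv")
        graph.to_graphml(
            out / f"{name}_graph.graphml",
            node_attrs={
                "community": metrics["community"].to_dict(),
                "betweenness": metrics["betweenness"].to_dict(),
                "hub": {k: bool(v) for k, v in metrics["hub"].items()},
            },
        )
        metrics.to_csv(out / f"{name}_metrics.csv")
        metrics[["community"]].to_csv(out / f"{name}_partition.csv")
        profiles = domain_means(metrics, battery)
        frame = domain_profiles_frame(profiles)
        frame.insert(0, "group", name)
        profile_rows.append(frame)
        graphs[name] = graph
        metric_tables[name] = metrics
        logger.info(
            "group %s: %d nodes, %d edges", name, graph.n_nodes, graph.n_edges
        )

    profiles_table = pd.concat(profile_rows, ignore_index=True)
    profiles_table.to_csv(out / "domain_profiles.csv", index=False)

    pairs = (
        list(config.comparison_pairs)
        if config.comparison_pairs
        else list(combinations(groups, 2))
    )
    results = []
    for metric in config.comparison_metrics:
        for a, b in pairs:
            results.append(
                mann_whitney_metrics(
                    metric_tables[a][metric],
                    metric_tables[b][metric],
                    measure=metric,
                    group_a=a,
                    group_b=b,
                    family_size=len(pairs),  # per-metric family
                )
            )
    comparison_table = comparisons_frame(results)
    comparison_table.to_csv(out / "comparisons.csv", index=False)

    consistency_table = consistency_frame(
        domain_consistency(scored, battery)
    )
    consistency_table.to_csv(out / "consistency.csv", index=False)

    manifest = {
        "cognet_version": _VERSION,
        "config": json.loads(json.dumps(asdict(config), default=list)),
        "groups": {
            name: {
                "n_subjects": int((cohort["group"] == name).sum()),
                "n_nodes": graphs[name].n_nodes,
                "n_edges": graphs[name].n_edges,
                "edge_seed": config.seed + idx,
                "louvain_seed": config.seed + idx,
            }
            for idx, name in enumerate(groups)
        },
    }
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)

    return {
        "cohort": scored,
        "graphs": graphs,
        "metrics": metric_tables,
        "domain_profiles": profiles_table,
        "comparisons": comparison_table,
        "consistency": consistency_table,
        "manifest": manifest,
    }
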