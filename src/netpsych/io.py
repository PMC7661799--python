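"""File formats, configuration and the end-to-end two-group pipeline.

Tables travel as CSV (a ``group`` column plus one column per measure) with a
YAML/JSON typing config declaring each measure continuous or ordinal with its
level range.  Networks export as weighted edge-list CSV, GraphML and JSON;
profiles, partitions and comparison reports as CSV/JSON.  All randomness
derives from one root seed via per-stage spawned seeds, and every report
carries a hash of the configuration that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np
import pandas as pd
import yaml

from . import __version__
from .centrality import CentralityProfile, centrality_profile
from .community import CommunityPartition, interpret_modularity, louvain
from .comparison import (
    BootstrapResult,
    ComparisonReport,
    bootstrap_networks,
    centrality_z_test,
    descriptive_tests,
)
from .datagen import GroupSpec, MeasureTable, VariableSpec, asd_td_specs, generate_group_sample
from .estimation import NetworkModel, estimate_network

__all__ = [
    "PipelineConfig",
    "Report",
    "run_pipeline",
    "read_measure_table",
    "write_measure_table",
    "read_variable_specs",
    "write_variable_specs",
    "read_group_spec",
    "write_group_spec",
    "write_network",
    "write_association",
    "network_to_graphml",
    "write_profile",
    "write_partition",
    "write_comparison",
]

logger = logging.getLogger(__name__)


# --- variable typing configs -----------------------------------------------

def _spec_to_dict(v: VariableSpec) -> dict:
    d = {"name": v.name, "kind": v.kind, "range": list(v.bounds)}
    if v.levels is not None:
        d["levels"] = v.levels
    return d


def write_variable_specs(variables: list[VariableSpec], path: str | Path) -> None:
    path = Path(path)
    payload = {"variables": [_spec_to_dict(v) for v in variables]}
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)


def read_variable_specs(path: str | Path) -> list[VariableSpec]:
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    out = []
    for d in payload["variables"]:
        out.append(
            VariableSpec(
                name=d["name"],
                kind=d["kind"],
                levels=d.get("levels"),
                bounds=tuple(d["range"]),
            )
        )
    return out


def read_group_spec(path: str | Path) -> GroupSpec:
    path = Path(path)
    with open(path) as fh:
        payload = json.load(fh) if path.suffix == ".json" else yaml.safe_load(fh)
    variables = [
        VariableSpec(
            name=d["name"], kind=d["kind"], levels=d.get("levels"), bounds=tuple(d["range"])
        )
        for d in payload["variables"]
    ]
    return GroupSpec(
        label=payload["label"],
        n=int(payload["n"]),
        variables=variables,
        precision=np.asarray(payload["precision"], dtype=float),
        thresholds={k: np.asarray(v, dtype=float) for k, v in payload["thresholds"].items()},
    )


def write_group_spec(spec: GroupSpec, path: str | Path) -> None:
    payload = {
        "label": spec.label,
        "n": spec.n,
        "variables": [_spec_to_dict(v) for v in spec.variables],
        "thresholds": {k: v.tolist() for k, v in spec.thresholds.items()},
        "precision": spec.precision.tolist(),
    }
    path = Path(path)
    with open(path, "w") as fh:
        if path.suffix == ".json":
            json.dump(payload, fh, indent=2)
        else:
            yaml.safe_dump(payload, fh, sort_keys=False)


# --- measure tables --------------------------------------------------------

def write_measure_table(table: MeasureTable, path: str | Path) -> None:
    table.data.to_csv(path, index=False)


def read_measure_table(path: str | Path, variables: list[VariableSpec]) -> MeasureTable:
    df = pd.read_csv(path)
    if MeasureTable.GROUP_COLUMN not in df.columns:
        raise ValueError(f"{path}: missing the {MeasureTable.GROUP_COLUMN!r} column")
    for v in variables:
        if v.name not in df.columns:
            raise ValueError(f"{path}: missing declared column {v.name!r}")
        if not pd.api.types.is_numeric_dtype(df[v.name]):
            raise ValueError(f"{path}: column {v.name!r} contains non-numeric values")
    return MeasureTable(df, variables)  # MeasureTable validates ranges


# --- network exports -------------------------------------------------------

def network_to_graphml(network: NetworkModel, path: str | Path) -> None:
    g = nx.Graph()
    g.add_nodes_from(network.nodes)
    for u, v, w in network.edges():
        g.add_edge(u, v, weight=w)
    nx.write_graphml(g, path)


def write_network(network: NetworkModel, path_base: str | Path) -> None:
    """Write edge-list CSV, GraphML and JSON next to each other."""
    base = Path(path_base)
    pd.DataFrame(network.edges(), columns=["node_i", "node_j", "weight"]).to_csv(
        base.with_suffix(".edges.csv"), index=False
    )
    network_to_graphml(network, base.with_suffix(".graphml"))
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(
            {
                "nodes": network.nodes,
                "weights": network.weights.tolist(),
                "lambda": network.lam,
                "bic": network.bic,
                "n": network.n,
            },
            fh,
            indent=2,
        )


def write_association(assoc, path_base: str | Path) -> None:
    """Correlations and p-values as CSV, method tags and n as a JSON sidecar."""
    base = Path(path_base)
    pd.DataFrame(assoc.r, index=assoc.names, columns=assoc.names).to_csv(
        base.with_suffix(".r.csv")
    )
    pd.DataFrame(assoc.p_value, index=assoc.names, columns=assoc.names).to_csv(
        base.with_suffix(".p.csv")
    )
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(
            {"names": assoc.names, "n": assoc.n, "method": assoc.method.tolist()},
            fh,
            indent=2,
        )


def write_profile(profile: CentralityProfile, path: str | Path) -> None:
    rows = [
        {"node": node, "metric": metric, "value": value}
        for metric in ("strength", "betweenness", "closeness")
        for node, value in zip(profile.nodes, getattr(profile, metric))
    ]
    path = Path(path)
    pd.DataFrame(rows).to_csv(path, index=False)
    with open(path.with_suffix(".json"), "w") as fh:
        json.dump(profile.as_dict(), fh, indent=2)


def write_partition(partition: CommunityPartition, path_base: str | Path) -> None:
    base = Path(path_base)
    pd.DataFrame(
        sorted(partition.assignment.items()), columns=["node", "community"]
    ).to_csv(base.with_suffix(".csv"), index=False)
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(
            {
                "assignment": partition.assignment,
                "Q": partition.Q,
                "n_communities": partition.n_communities,
                "seed": partition.seed,
                "restarts": partition.restarts,
            },
            fh,
            indent=2,
        )


def write_comparison(report: ComparisonReport, path_base: str | Path) -> None:
    base = Path(path_base)
    report.table.to_csv(base.with_suffix(".csv"), index=False)
    with open(base.with_suffix(".json"), "w") as fh:
        json.dump(
            {
                "groups": list(report.groups),
                "m": report.m,
                "alpha": report.alpha,
                "cells": report.table.replace({np.nan: None}).to_dict(orient="records"),
            },
            fh,
            indent=2,
        )


# --- pipeline --------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Everything needed to run the two-group analysis end to end."""

    input_csv: str | None = None  # if None, simulate from the built-in specs
    variables_config: str | None = None
    group_a: str = "TD"
    group_b: str = "ASD"
    alpha_filter: float = 0.05  # correlation significance filtering
    alpha_compare: float = 0.05  # family-wise level for group comparisons
    grid_size: int = 100
    B: int = 1000
    restarts: int = 20
    seed: int = 0
    output_dir: str = "netpsych-output"
    signed_strength: bool = False
    scaled_closeness: bool = True

    def __post_init__(self) -> None:
        for name in ("alpha_filter", "alpha_compare"):
            a = getattr(self, name)
            if not 0 < a < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {a}")

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            payload = yaml.safe_load(fh) or {}
        return PipelineConfig(**payload)

    def config_hash(self) -> str:
        """Hash of the analysis-relevant settings (output location excluded)."""
        payload = dataclasses.asdict(self)
        payload.pop("output_dir")
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True).encode()
        ).hexdigest()[:16]


@dataclass
class GroupResult:
    label: str
    network: NetworkModel
    profile: CentralityProfile
    partition: CommunityPartition
    bootstrap: BootstrapResult


@dataclass
class Report:
    groups: dict[str, GroupResult]
    comparison: ComparisonReport
    descriptives: pd.DataFrame
    provenance: dict = field(default_factory=dict)

    def summary(self) -> dict:
        out: dict = {"provenance": self.provenance, "groups": {}}
        for label, g in self.groups.items():
            out["groups"][label] = {
                "lambda": g.network.lam,
                "bic": g.network.bic,
                "edge_count": g.network.edge_count(),
                "Q": g.partition.Q,
                "modularity_label": interpret_modularity(g.partition.Q),
                "n_communities": g.partition.n_communities,
                "bootstrap_failures": g.bootstrap.failures,
            }
        out["comparison"] = {
            "m": self.comparison.m,
            "alpha": self.comparison.alpha,
            "n_significant": int(self.comparison.table["significant"].sum()),
        }
        out["descriptives"] = {
            "n_significant": int(self.descriptives["significant"].sum())
        }
        return out


def _stage_seeds(seed: int, labels: list[str]) -> dict[str, int]:
    children = np.random.SeedSequence(seed).spawn(len(labels))
    return {
        label: int(child.generate_state(1)[0] % (2**31))
        for label, child in zip(labels, children)
    }


def run_pipeline(config: PipelineConfig) -> Report:
    """Per group: estimate, centrality, communities, bootstrap; then compare."""
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    seeds = _stage_seeds(
        config.seed,
        ["simulate_a", "simulate_b", "louvain_a", "louvain_b", "boot_a", "boot_b"],
    )

    if config.input_csv is None:
        spec_a, spec_b = asd_td_specs()
        table_a = generate_group_sample(spec_a, seeds["simulate_a"])
        table_b = generate_group_sample(spec_b, seeds["simulate_b"])
        config = dataclasses.replace(config, group_a=spec_a.label, group_b=spec_b.label)
        variables = spec_a.variables
    else:
        if config.variables_config is None:
            raise ValueError("input_csv requires a variables_config typing file")
        variables = read_variable_specs(config.variables_config)
        full = read_measure_table(config.input_csv, variables)
        for label in (config.group_a, config.group_b):
            if label not in full.groups:
                raise ValueError(f"group column has no rows labelled {label!r}")
        table_a = full.select_group(config.group_a)
        table_b = full.select_group(config.group_b)

    results: dict[str, GroupResult] = {}
    for label, table, tag in (
        (config.group_a, table_a, "a"),
        (config.group_b, table_b, "b"),
    ):
        logger.info("pipeline: estimating network for group %r (n=%d)", label, table.n)
        net = estimate_network(
            table, alpha=config.alpha_filter, grid_size=config.grid_size
        )
        profile = centrality_profile(
            net, signed=config.signed_strength, scaled_closeness=config.scaled_closeness
        )
        partition = louvain(net, seed=seeds[f"louvain_{tag}"], restarts=config.restarts)
        boot = bootstrap_networks(
            table,
            B=config.B,
            seed=seeds[f"boot_{tag}"],
            alpha=config.alpha_filter,
            grid_size=config.grid_size,
        )
        results[label] = GroupResult(label, net, profile, partition, boot)
        write_measure_table(table, outdir / f"table_{label}.csv")
        write_network(net, outdir / f"network_{label}")
        write_profile(profile, outdir / f"centrality_{label}.csv")
        write_partition(partition, outdir / f"communities_{label}")
        logger.info(
            "pipeline: group %r lambda*=%.4g edges=%d Q=%.3f (%d communities)",
            label, net.lam, net.edge_count(), partition.Q, partition.n_communities,
        )

    comparison = centrality_z_test(
        results[config.group_a].bootstrap,
        results[config.group_b].bootstrap,
        alpha=config.alpha_compare,
    )
    descriptives = descriptive_tests(table_a, table_b, alpha=config.alpha_compare)
    write_comparison(comparison, outdir / "comparison")
    descriptives.to_csv(outdir / "descriptives.csv", index=False)

    report = Report(
        groups=results,
        comparison=comparison,
        descriptives=descriptives,
        provenance={
            "config_hash": config.config_hash(),
            "seed": config.seed,
            "stage_seeds": seeds,
            "netpsych_version": __version__,
        },
    )
    with open(outdir / "report.json", "w") as fh:
        json.dump(report.summary(), fh, indent=2)
    return report
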