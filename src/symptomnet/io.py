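"""File formats: edge-list TSV, GraphML, partition/centrality TSV, JSON
run manifest, YAML configs, cohort CSV with ground-truth sidecar, and
input validation."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict
from pathlib import Path
from typing import Optional

import igraph as ig
import numpy as np
import pandas as pd
import yaml

from .data import RatingMatrix
from .estimation import NetworkModel, PipelineConfig
from .generate import GeneratorConfig

__all__ = [
    "write_edgelist",
    "write_graphml",
    "write_partition",
    "write_centrality",
    "write_manifest",
    "load_pipeline_config",
    "load_generator_config",
    "validate_input",
    "save_results",
]


def write_edgelist(model: NetworkModel, path) -> None:
    df = pd.DataFrame(model.edges(), columns=["node_i", "node_j", "weight"])
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")


def write_graphml(model: NetworkModel, path) -> None:
    A = model.adjacency
    g = ig.Graph.Weighted_Adjacency(A.tolist(), mode="undirected",
                                    attr="weight", loops=False)
    g.vs["name"] = list(model.nodes)
    g.write_graphml(str(path))


def write_partition(partition, path) -> None:
    df = pd.DataFrame({"node": partition.labels.index,
                       "community": partition.labels.to_numpy()})
    df.to_csv(path, sep="\t", index=False)


def write_centrality(centrality: pd.DataFrame, path,
                     z_standardised: bool = False) -> None:
    out = centrality.copy()
    if z_standardised:
        for col in out.columns:
            if col == "community":
                continue
            out[col] = (out[col] - out[col].mean()) / out[col].std(ddof=1)
    out.to_csv(path, sep="\t", float_format="%.10g")


def _config_hash(config) -> str:
    payload = json.dumps(asdict(config), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]


def write_manifest(results, path, seed: Optional[int] = None) -> None:
    m = results.model
    counts = results.preprocessing_counts()
    manifest = {
        "config": asdict(results.config),
        "config_hash": _config_hash(results.config),
        "seed": seed,
        "n_input": counts["n_input"],
        "n_analysed": counts["n_analysed"],
        "cells_replaced": counts["cells_replaced"],
        "rows_removed": counts["rows_removed"],
        "effective_n": results.correlations.effective_n,
        "psd_repaired": bool(results.correlations.repaired),
        "lambda_selected": m.lambda_selected,
        "gamma": m.gamma,
        "tau": m.tau,
        "thresholded": m.thresholded,
        "edge_count": m.edge_count,
        "n_communities": results.partition.n_communities,
        "modularity": results.partition.modularity,
    }
    with open(path, "w") as fh:
        json.dump(manifest, fh, indent=2)


def save_results(results, outdir, seed: Optional[int] = None) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    write_edgelist(results.model, outdir / "edges.tsv")
    write_graphml(results.model, outdir / "network.graphml")
    write_partition(results.partition, outdir / "communities.tsv")
    write_centrality(results.centrality, outdir / "centrality.tsv")
    write_centrality(results.centrality, outdir / "centrality_z.tsv",
                     z_standardised=True)
    write_manifest(results, outdir / "manifest.json", seed=seed)


def load_pipeline_config(path) -> PipelineConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    raw.pop("orientation", None)
    raw.pop("bounds", None)
    return PipelineConfig(**raw)


def load_generator_config(path) -> GeneratorConfig:
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if "partial_corr_range" in raw:
        raw["partial_corr_range"] = tuple(raw["partial_corr_range"])
    if "score_bounds" in raw and raw["score_bounds"] is not None:
        raw["score_bounds"] = tuple(raw["score_bounds"]) \
            if np.isscalar(raw["score_bounds"][0]) else raw["score_bounds"]
    return GeneratorConfig(**raw)


def load_orientation_bounds(path):
    """Read a YAML map of variable -> {orientation: bool, bounds: [lo, hi]}."""
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    orientation = {}
    bounds = {}
    for var, spec in raw.items():
        if spec is None:
            continue
        if "orientation" in spec:
            orientation[var] = bool(spec["orientation"])
        if "bounds" in spec and spec["bounds"] is not None:
            bounds[var] = tuple(spec["bounds"])
    return orientation or None, bounds or None


def validate_input(path) -> list:
    """Validate a cohort CSV; returns a list of issue dicts
    ({level, message}), empty when the file is clean."""
    issues = []
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    import csv

    with open(path, newline="") as fh:
        cols = next(csv.reader(fh), [])
    dupes = {c for c in cols if cols.count(c) > 1}
    for c in sorted(dupes):
        issues.append({"level": "fatal", "message": f"duplicated column name: {c}"})
    df = pd.read_csv(path, na_values=["NA", ""])
    for c in df.columns:
        col = pd.to_numeric(df[c], errors="coerce")
        n_bad = int((col.isna() & df[c].notna()).sum())
        if n_bad:
            issues.append({"level": "fatal",
                           "message": f"column {c}: {n_bad} non-numeric cells"})
            continue
        if col.isna().all():
            issues.append({"level": "fatal",
                           "message": f"column {c}: all values missing"})
        elif col.dropna().nunique() == 1:
            issues.append({"level": "warning",
                           "message": f"column {c}: constant values"})
    return issues
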