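"""Node-level inference: strength, expected influence, bridge strength,
nodewise predictability (R^2), and the centrality-versus-SD bias check.

Strength sums absolute incident edge weights; expected influence is the
signed analogue; bridge strength sums absolute weights to nodes outside
the node's own community.  Predictability is the variance of a node
explained by all other nodes in a listwise-complete nodewise regression.
"""

from __future__ import annotations

import itertools
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .community import CommunityPartition
from .data import RatingMatrix
from .estimation import NetworkModel

__all__ = [
    "strength",
    "expected_influence",
    "bridge_strength",
    "predictability",
    "centrality_table",
    "centrality_sd_bias",
]


def _node_index(model: NetworkModel, node) -> int:
    try:
        return model.nodes.index(node)
    except ValueError:
        raise KeyError(f"node {node!r} not in model") from None


def strength(model: NetworkModel, node=None):
    """Sum of absolute incident edge weights (per node or one node)."""
    s = np.abs(model.adjacency).sum(axis=1)
    if node is None:
        return pd.Series(s, index=model.nodes)
    return float(s[_node_index(model, node)])


def expected_influence(model: NetworkModel, node=None):
    """Signed sum of incident edge weights."""
    s = model.adjacency.sum(axis=1)
    if node is None:
        return pd.Series(s, index=model.nodes)
    return float(s[_node_index(model, node)])


def bridge_strength(model: NetworkModel, partition: CommunityPartition, node=None):
    """Sum of absolute edge weights from a node to nodes in other
    communities."""
    missing = [v for v in model.nodes if v not in partition.labels.index]
    if missing:
        raise KeyError(f"partition does not cover nodes: {missing}")
    lab = np.asarray([partition.labels[v] for v in model.nodes])
    other = lab[:, None] != lab[None, :]
    s = (np.abs(model.adjacency) * other).sum(axis=1)
    if node is None:
        return pd.Series(s, index=model.nodes)
    return float(s[_node_index(model, node)])


def predictability(data: RatingMatrix, model: NetworkModel,
                   min_rows_factor: int = 5) -> pd.Series:
    """Nodewise R^2 over listwise-complete rows of the (transformed) data.

    Each node is regressed by OLS on all other non-covariate nodes;
    R^2 = 1 - RSS/TSS clipped to [0, 1].
    """
    cols = [v for v in model.nodes]
    df = data.values[cols].dropna(axis=0)
    n, p = df.shape
    if n < min_rows_factor * p:
        raise ValueError(
            f"only {n} listwise-complete rows for {p} nodes; "
            f"need at least {min_rows_factor * p}"
        )
    X = df.to_numpy()
    out = {}
    for j, name in enumerate(cols):
        y = X[:, j]
        Z = np.delete(X, j, axis=1)
        Z1 = np.column_stack([np.ones(n), Z])
        beta, *_ = np.linalg.lstsq(Z1, y, rcond=None)
        resid = y - Z1 @ beta
        tss = ((y - y.mean()) ** 2).sum()
        r2 = 1.0 - resid @ resid / tss if tss > 0 else 0.0
        out[name] = float(np.clip(r2, 0.0, 1.0))
    return pd.Series(out)


def centrality_table(model: NetworkModel, partition: CommunityPartition,
                     data: Optional[RatingMatrix] = None) -> pd.DataFrame:
    """Assemble the per-node centrality table (strength, expected
    influence, bridge strength, community, and predictability when data
    are supplied)."""
    tab = pd.DataFrame({
        "strength": strength(model),
        "expected_influence": expected_influence(model),
        "bridge_strength": bridge_strength(model, partition),
        "community": [int(partition.labels[v]) for v in model.nodes],
    }, index=pd.Index(model.nodes, name="node"))
    if data is not None:
        tab["predictability"] = predictability(data, model)
    return tab


def _exact_spearman_p(x: np.ndarray, y: np.ndarray, rho_obs: float,
                      chunk: int = 200_000) -> float:
    """Two-sided exact permutation p-value for Spearman's rho (small n)."""
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    n = len(rx)
    rx = (rx - rx.mean()) / rx.std()
    ry = (ry - ry.mean()) / ry.std()
    total = math.factorial(n)
    hits = 0
    seen = 0
    perms = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(perms, chunk))
        if not block:
            break
        P = np.asarray(block)
        rhos = (ry[P] * rx).mean(axis=1)
        hits += int(np.count_nonzero(np.abs(rhos) >= abs(rho_obs) - 1e-12))
        seen += len(block)
    assert seen == total
    return hits / total


def centrality_sd_bias(centrality: pd.DataFrame, data: RatingMatrix,
                       indices: Sequence[str] = ("strength", "expected_influence",
                                                 "bridge_strength"),
                       exact_max_n: int = 10) -> pd.DataFrame:
    """Spearman correlation of each centrality index with the
    per-variable raw-score SDs.

    A strong association would suggest centrality is an artefact of
    differential node variability.  Exact permutation p-values are used
    for up to ``exact_max_n`` nodes, asymptotic ones beyond.
    """
    nodes = list(centrality.index)
    if len(nodes) < 4:
        raise ValueError("need at least 4 nodes")
    sds = data.values[nodes].std(ddof=1).to_numpy()
    if np.allclose(sds, sds[0]):
        raise ValueError("per-variable SDs are constant; correlation undefined")
    rows = {}
    for idx in indices:
        c = centrality[idx].to_numpy()
        rho, p_asym = stats.spearmanr(c, sds)
        if len(nodes) <= exact_max_n:
            p = _exact_spearman_p(c, sds, rho)
        else:
            p = p_asym
        rows[idx] = {"rho": float(rho), "p": float(p)}
    return pd.DataFrame(rows).T
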