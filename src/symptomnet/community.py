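"""Walktrap community detection and weighted modularity.

Random walks require nonnegative weights, so both the walks and the
modularity use absolute partial correlations — the standard convention
for (almost entirely positive) partial-correlation symptom networks.
The Walktrap merge sequence is cut at the partition maximising
modularity; the whole procedure is deterministic (transition
probabilities are computed analytically, no sampling).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import igraph as ig
import numpy as np
import pandas as pd

from .estimation import NetworkModel

__all__ = ["CommunityPartition", "walktrap", "modularity"]


@dataclass
class CommunityPartition:
    labels: pd.Series  # node name -> community id
    modularity: float
    merge_sequence: list = field(default_factory=list)  # (a, b, merge order)
    walk_length: int = 4

    @property
    def n_communities(self) -> int:
        return int(self.labels.nunique())

    def members(self, community_id) -> list:
        return list(self.labels.index[self.labels == community_id])

    def as_dict(self) -> dict:
        return {k: int(v) for k, v in self.labels.items()}


def _abs_graph(model: NetworkModel) -> ig.Graph:
    A = np.abs(model.adjacency)
    g = ig.Graph.Weighted_Adjacency(A.tolist(), mode="undirected", attr="weight",
                                    loops=False)
    g.vs["name"] = list(model.nodes)
    return g


def walktrap(model: NetworkModel, t: int = 4) -> CommunityPartition:
    """Walktrap communities of the absolute-weight network.

    Short random walks of length ``t`` define a node distance;
    Ward-style agglomeration merges communities and the merge tree is cut
    at maximum modularity.  Isolated nodes become singleton communities;
    an edgeless network returns all-singletons with Q = 0.
    """
    if model.p < 2:
        raise ValueError("need at least 2 nodes for community detection")
    g = _abs_graph(model)
    if g.ecount() == 0:
        labels = pd.Series(range(model.p), index=model.nodes)
        return CommunityPartition(labels=labels, modularity=0.0, walk_length=t)
    dendro = g.community_walktrap(weights="weight", steps=t)
    clustering = dendro.as_clustering()  # cut maximising modularity
    labels = pd.Series(clustering.membership, index=model.nodes)
    q = modularity(model, labels)
    merges = [(int(a), int(b), k) for k, (a, b) in enumerate(dendro.merges)]
    return CommunityPartition(labels=labels, modularity=q,
                              merge_sequence=merges, walk_length=t)


def modularity(model: NetworkModel, labels: Mapping | pd.Series | Sequence) -> float:
    """Weighted modularity Q on absolute edge weights:
    Q = (1/2m) sum_ij [a_ij - k_i k_j / (2m)] delta(c_i, c_j)."""
    if isinstance(labels, (pd.Series, dict)):
        lab = np.asarray([labels[v] for v in model.nodes])
    else:
        lab = np.asarray(list(labels))
        if lab.size != model.p:
            raise ValueError("labels must cover all nodes")
    A = np.abs(model.adjacency)
    two_m = A.sum()  # = 2m on the symmetric matrix
    if two_m == 0:
        return 0.0
    k = A.sum(axis=1)
    same = lab[:, None] == lab[None, :]
    Q = ((A - np.outer(k, k) / two_m) * same).sum() / two_m
    return float(Q)
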