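"""Model/Results facade tying the pipeline stages together.

``SymptomNetwork`` is built from data (a :class:`RatingMatrix` or a flat
DataFrame) plus a :class:`PipelineConfig`; ``fit()`` runs cleaning,
transformation, correlation, glasso/EBIC selection, thresholding,
community detection and centrality, and returns a
:class:`NetworkResults` carrying the estimates with ``summary()``,
bootstrap methods, comparison and plotting.
"""

from __future__ import annotations

from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import stability as _stability
from .centrality import centrality_sd_bias, centrality_table
from .community import CommunityPartition, walktrap
from .data import RatingMatrix
from .estimation import NetworkModel, PipelineConfig, estimate_network
from .preprocessing import CorrelationEstimate

__all__ = ["SymptomNetwork", "NetworkResults"]


class SymptomNetwork:
    """Regularised partial-correlation network model of rating-scale data.

    Parameters
    ----------
    data : RatingMatrix
        Persons x subscales ratings with orientation flags and optional
        age/group columns.
    config : PipelineConfig, optional
        Estimation switches; defaults to the headline variant
        (nonparanormal transform, pairwise correlations, EBIC glasso with
        gamma=0.5, theoretical-bound threshold, age as covariate node).

    Examples
    --------
    >>> net = SymptomNetwork.from_dataframe(df, age_col="age")
    >>> res = net.fit()
    >>> print(res.summary())
    """

    def __init__(self, data: RatingMatrix, config: Optional[PipelineConfig] = None):
        self.data = data
        self.config = config if config is not None else PipelineConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame,
                       orientation: Optional[Mapping[str, bool]] = None,
                       bounds: Optional[Mapping[str, tuple]] = None,
                       age_col: Optional[str] = "age",
                       group_col: Optional[str] = "group",
                       config: Optional[PipelineConfig] = None) -> "SymptomNetwork":
        data = RatingMatrix.from_dataframe(df, orientation=orientation,
                                           bounds=bounds, age_col=age_col,
                                           group_col=group_col)
        return cls(data, config=config)

    def fit(self) -> "NetworkResults":
        model, clean, transformed, est, full_model = estimate_network(
            self.data, self.config, return_intermediates=True)
        partition = walktrap(model, t=self.config.walktrap_steps)
        centrality = centrality_table(model, partition, data=transformed)
        return NetworkResults(self, model=model, partition=partition,
                              centrality=centrality, clean=clean,
                              transformed=transformed, correlations=est,
                              full_model=full_model)


class NetworkResults:
    """Fitted network with communities, centrality and stability methods."""

    def __init__(self, parent: SymptomNetwork, model: NetworkModel,
                 partition: CommunityPartition, centrality: pd.DataFrame,
                 clean: RatingMatrix, transformed: RatingMatrix,
                 correlations: CorrelationEstimate, full_model: NetworkModel):
        self.model = model
        self.partition = partition
        self.centrality = centrality
        self.clean = clean
        self.transformed = transformed
        self.correlations = correlations
        self.full_model = full_model
        self.config = parent.config
        self.data = parent.data

    # -- convenience views ------------------------------------------------
    @property
    def adjacency(self) -> pd.DataFrame:
        return pd.DataFrame(self.model.adjacency, index=self.model.nodes,
                            columns=self.model.nodes)

    def edges_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.model.edges(),
                            columns=["node_i", "node_j", "weight"])

    def preprocessing_counts(self) -> dict:
        out = {"n_input": self.data.n, "n_analysed": self.clean.n,
               "cells_replaced": 0, "rows_removed": 0}
        for entry in self.clean.log:
            if entry.get("step") == "univariate_outliers":
                out["cells_replaced"] = entry["replaced"]
            if entry.get("step") == "multivariate_outliers":
                out["rows_removed"] = len(entry["removed"])
        return out

    def sd_bias(self, **kwargs) -> pd.DataFrame:
        """Spearman association of each centrality index with raw-score SDs."""
        clean_no_age = self.clean
        return centrality_sd_bias(self.centrality, clean_no_age, **kwargs)

    # -- stability ---------------------------------------------------------
    def bootstrap_edges(self, B: int = 2000, seed: Optional[int] = None,
                        **kwargs) -> "_stability.StabilityReport":
        return _stability.bootstrap_edges(self.clean, self.config, B=B,
                                          seed=seed, **kwargs)

    def casedrop_stability(self, B: int = 2000, seed: Optional[int] = None,
                           **kwargs) -> "_stability.StabilityReport":
        return _stability.casedrop_cs(self.clean, self.config, B=B, seed=seed,
                                      **kwargs)

    def compare(self, other) -> float:
        other_model = other.model if isinstance(other, NetworkResults) else other
        return _stability.compare_networks(self.model, other_model)

    # -- reporting ---------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        counts = self.preprocessing_counts()
        lines = [
            "Symptom network (regularised partial correlations)",
            "=" * 52,
            f"persons analysed       {counts['n_analysed']} "
            f"(of {counts['n_input']}; {counts['rows_removed']} multivariate "
            f"outlier rows removed, {counts['cells_replaced']} cells set missing)",
            f"nodes                  {m.p}"
            + (f" (+ covariates: {', '.join(self.full_model.covariate_nodes)})"
               if self.full_model.covariate_nodes else ""),
            f"correlations           {self.correlations.method}"
            f" (effective n = {self.correlations.effective_n}"
            f"{', PSD-repaired' if self.correlations.repaired else ''})",
            f"penalty (EBIC gamma)   lambda = {m.lambda_selected:.4f} "
            f"(gamma = {m.gamma})",
            f"threshold tau          {m.tau:.4f}" if m.thresholded
            else "threshold tau          (not applied)",
            f"edges                  {m.edge_count}",
            f"communities (Walktrap) {self.partition.n_communities} "
            f"(Q = {self.partition.modularity:.3f})",
            "",
            "Centrality (top 5 by strength):",
        ]
        top = self.centrality.sort_values("strength", ascending=False).head(5)
        lines.append(top.to_string(float_format=lambda v: f"{v:.3f}"))
        return "\n".join(lines)

    def plot(self, ax=None):
        """Basic circular-layout network plot: edge width by |weight|,
        green/red for sign, node colour by community."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(7, 7))
        p = self.model.p
        theta = 2 * np.pi * np.arange(p) / p
        xy = np.column_stack([np.cos(theta), np.sin(theta)])
        W = self.model.adjacency
        wmax = np.abs(W).max() or 1.0
        for i in range(p):
            for j in range(i + 1, p):
                w = W[i, j]
                if w == 0:
                    continue
                ax.plot(xy[[i, j], 0], xy[[i, j], 1],
                        color="forestgreen" if w > 0 else "firebrick",
                        linewidth=3.0 * abs(w) / wmax, alpha=0.7, zorder=1)
        comm = np.asarray([self.partition.labels[v] for v in self.model.nodes])
        cmap = plt.get_cmap("tab10")
        ax.scatter(xy[:, 0], xy[:, 1], s=300, c=[cmap(c % 10) for c in comm],
                   edgecolors="black", zorder=2)
        for (x, y), name in zip(xy * 1.12, self.model.nodes):
            ax.annotate(name, (x, y), ha="center", va="center", fontsize=8)
        ax.set_xlim(-1.3, 1.3)
        ax.set_ylim(-1.3, 1.3)
        ax.set_aspect("equal")
        ax.axis("off")
        return ax

    def save(self, outdir, seed: Optional[int] = None) -> None:
        from .io import save_results

        save_results(self, outdir, seed=seed)
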