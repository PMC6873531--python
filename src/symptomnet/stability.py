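"""Estimation robustness: bootstrap edge intervals, case-dropping
correlation-stability (CS) coefficients, and network comparison.

Two resampling schemes are provided.  The nonparametric edge bootstrap
redraws rows with replacement and re-runs the entire estimation
(transform, correlations, glasso path at the same gamma, threshold) per
replicate, yielding per-edge quantile intervals and the percentage of
replicates in which each edge survived (%-nonzero).  The case-dropping
bootstrap discards a growing proportion of rows and asks how far the
replicate centrality vectors stay correlated with the full-sample ones;
CS(cor) is the largest drop proportion at which at least ``prob`` of the
replicates correlate at ``cor`` or better.

All randomness flows from one SeedSequence; each replicate consumes its
own spawned substream, so results are identical regardless of how the
replicates are scheduled.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .centrality import bridge_strength, expected_influence, strength
from .community import walktrap
from .data import RatingMatrix
from .estimation import NetworkModel, PipelineConfig, fit_from_clean, estimate_network

__all__ = [
    "StabilityReport",
    "bootstrap_edges",
    "casedrop_cs",
    "cs_coefficient",
    "compare_networks",
    "subgroup_networks",
]

DEFAULT_PROPORTIONS = tuple(np.round(np.arange(0.10, 0.751, 0.05), 2))


@dataclass
class StabilityReport:
    """Container for bootstrap results.

    ``edges`` (edge bootstrap): one row per node pair with the sample
    weight, bootstrap mean, overall and nonzero-conditional 95% quantile
    intervals, and %-nonzero.  ``cs`` / ``curves`` (case-dropping): the
    CS coefficient per centrality index and the full replicate
    correlation tables behind it.
    """

    B: int
    seed: Optional[int]
    edges: Optional[pd.DataFrame] = None
    cs: Optional[pd.Series] = None
    curves: dict = field(default_factory=dict)  # index -> DataFrame (prop x replicate)
    proportions: tuple = ()
    cor_threshold: float = 0.7
    prob: float = 0.95
    n_failed: int = 0
    n_total: int = 0


def _resample_fit(clean: RatingMatrix, config: PipelineConfig, rng,
                  subsample: Optional[int] = None) -> NetworkModel:
    n = clean.n
    if subsample is None:
        pos = rng.integers(0, n, size=n)
    else:
        pos = rng.choice(n, size=subsample, replace=False)
    labels = clean.values.index[pos]
    return fit_from_clean(clean.subset_rows(labels), config)


def bootstrap_edges(clean: RatingMatrix, config: Optional[PipelineConfig] = None,
                    B: int = 2000, seed: Optional[int] = None,
                    max_fail_frac: float = 0.05) -> StabilityReport:
    """Nonparametric bootstrap of all edge weights.

    ``clean`` should be the oriented, outlier-treated data (cleaning is
    not repeated per replicate; the transform and estimation are).
    Failed replicates are logged and excluded; more than
    ``max_fail_frac`` failures aborts.
    """
    if B < 100:
        raise ValueError("need at least 100 bootstrap replicates")
    if config is None:
        config = PipelineConfig()
    full = fit_from_clean(clean, config)
    p = full.p
    iu = np.triu_indices(p, k=1)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(B)
    draws = np.empty((B, iu[0].size))
    ok = np.zeros(B, dtype=bool)
    for b in range(B):
        rng = np.random.default_rng(children[b])
        try:
            model = _resample_fit(clean, config, rng)
            if model.nodes != full.nodes:
                raise RuntimeError("replicate node set mismatch")
            draws[b] = model.adjacency[iu]
            ok[b] = True
        except Exception as exc:  # noqa: BLE001 - replicate-level failure policy
            warnings.warn(f"bootstrap replicate {b} failed: {exc}")
    n_failed = int(B - ok.sum())
    if n_failed > max_fail_frac * B:
        raise RuntimeError(f"{n_failed}/{B} bootstrap replicates failed")
    W = draws[ok]

    nonzero = W != 0
    with np.errstate(invalid="ignore"):
        pct_nonzero = 100.0 * nonzero.mean(axis=0)
    rows = []
    for k, (i, j) in enumerate(zip(*iu)):
        col = W[:, k]
        nz = col[nonzero[:, k]]
        rows.append({
            "node_i": full.nodes[i],
            "node_j": full.nodes[j],
            "sample": float(full.adjacency[i, j]),
            "boot_mean": float(col.mean()),
            "boot_min": float(col.min()),
            "boot_max": float(col.max()),
            "q2.5": float(np.quantile(col, 0.025)),
            "q97.5": float(np.quantile(col, 0.975)),
            "q2.5_nonzero": float(np.quantile(nz, 0.025)) if nz.size else np.nan,
            "q97.5_nonzero": float(np.quantile(nz, 0.975)) if nz.size else np.nan,
            "pct_nonzero": float(pct_nonzero[k]),
        })
    edges = pd.DataFrame(rows)
    return StabilityReport(B=B, seed=seed, edges=edges, n_failed=n_failed,
                           n_total=B)


def _centrality_vectors(model: NetworkModel, partition,
                        indices: Sequence[str]) -> dict:
    out = {}
    for idx in indices:
        if idx == "strength":
            out[idx] = strength(model)
        elif idx == "expected_influence":
            out[idx] = expected_influence(model)
        elif idx == "bridge_strength":
            out[idx] = bridge_strength(model, partition)
        else:
            raise ValueError(f"unknown centrality index {idx!r}")
    return out


def cs_coefficient(curves: Mapping[float, Sequence[float]],
                   cor_threshold: float = 0.7, prob: float = 0.95) -> float:
    """CS(cor_threshold): the largest drop proportion at which at least
    ``prob`` of replicate correlations reach ``cor_threshold``; 0 if
    none does."""
    passing = [
        float(p) for p, rs in curves.items()
        if len(rs) > 0 and np.mean(np.asarray(rs) >= cor_threshold) >= prob
    ]
    return max(passing) if passing else 0.0


def casedrop_cs(clean: RatingMatrix, config: Optional[PipelineConfig] = None,
                indices: Sequence[str] = ("strength", "expected_influence",
                                          "bridge_strength"),
                proportions: Sequence[float] = DEFAULT_PROPORTIONS,
                B: int = 2000, cor_threshold: float = 0.7, prob: float = 0.95,
                seed: Optional[int] = None) -> StabilityReport:
    """Case-dropping bootstrap of centrality stability.

    For each drop proportion pi, ``B`` subsamples keep ceil((1-pi)*n)
    rows without replacement; the pipeline is re-run and each replicate's
    centrality vector is correlated (Pearson) with the full-sample one.
    Communities for bridge strength stay frozen at the full-sample
    partition so replicate values are comparable.
    """
    if config is None:
        config = PipelineConfig()
    if any(not (0.0 < float(p) < 1.0) for p in proportions):
        raise ValueError("drop proportions must lie in (0, 1)")
    full = fit_from_clean(clean, config)
    partition = walktrap(full, t=config.walktrap_steps)
    full_vecs = _centrality_vectors(full, partition, indices)

    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(proportions) * B)
    n = clean.n
    curves = {idx: {} for idx in indices}
    n_failed = 0
    for k, prop in enumerate(proportions):
        keep = int(np.ceil((1.0 - prop) * n))
        rs = {idx: [] for idx in indices}
        for b in range(B):
            rng = np.random.default_rng(children[k * B + b])
            try:
                model = _resample_fit(clean, config, rng, subsample=keep)
                vecs = _centrality_vectors(model, partition, indices)
                for idx in indices:
                    x = full_vecs[idx].to_numpy()
                    y = vecs[idx].reindex(full_vecs[idx].index).to_numpy()
                    if np.std(x) == 0 or np.std(y) == 0:
                        rs[idx].append(np.nan)
                    else:
                        rs[idx].append(float(np.corrcoef(x, y)[0, 1]))
            except Exception as exc:  # noqa: BLE001
                n_failed += 1
                warnings.warn(
                    f"case-dropping replicate failed at proportion {prop}: {exc}")
        for idx in indices:
            curves[idx][float(prop)] = rs[idx]

    cs = pd.Series({
        idx: cs_coefficient(curves[idx], cor_threshold=cor_threshold, prob=prob)
        for idx in indices
    }, name="CS")
    curve_frames = {
        idx: pd.DataFrame.from_dict(curves[idx], orient="index")
        for idx in indices
    }
    return StabilityReport(B=B, seed=seed, cs=cs, curves=curve_frames,
                           proportions=tuple(float(p) for p in proportions),
                           cor_threshold=cor_threshold, prob=prob,
                           n_failed=n_failed, n_total=len(proportions) * B)


def compare_networks(a: NetworkModel, b: NetworkModel) -> float:
    """Pearson correlation of the vectorised strict lower triangles of
    two adjacency matrices over the same node set."""
    if a.nodes != b.nodes:
        raise ValueError("networks must share an identical node set")
    il = np.tril_indices(a.p, k=-1)
    x, y = a.adjacency[il], b.adjacency[il]
    if np.std(x) == 0 or np.std(y) == 0:
        raise ValueError("zero-variance edge vector; correlation undefined")
    return float(np.corrcoef(x, y)[0, 1])


def subgroup_networks(data: RatingMatrix, config: Optional[PipelineConfig] = None,
                      min_size: int = 100, warn_size: int = 300):
    """Estimate one network per group label and compare each with the
    full-sample network.

    Returns ``(models, comparisons)``: a dict group -> NetworkModel and a
    Series of adjacency correlations versus the full-sample network.
    """
    if data.group is None:
        raise ValueError("data has no group labels")
    if config is None:
        config = PipelineConfig()
    full = estimate_network(data, config)
    models, comps = {}, {}
    for g, idx in data.group.groupby(data.group).groups.items():
        size = len(idx)
        if size < min_size:
            raise ValueError(f"group {g!r} has only {size} rows (< {min_size})")
        if size < warn_size:
            warnings.warn(
                f"group {g!r} has {size} rows; subgroup network may not be "
                "estimated with sufficient accuracy")
        sub = data.subset_rows(idx)
        models[g] = estimate_network(sub, config)
        comps[g] = compare_networks(full, models[g])
    return models, pd.Series(comps, name="adjacency_correlation")
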