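"""Regularised partial-correlation network estimation.

The estimator is the graphical lasso run over a log-spaced penalty path,
with the penalty chosen by the Extended Bayesian Information Criterion
(EBIC, hyperparameter gamma, default 0.5), optionally followed by a
theoretical-bound threshold tau = sqrt(log(p(p-1)/2) / n) that zeroes
small surviving edges under a strong sparsity assumption.  Edge weights
are the regularised partial correlations
w_ij = -theta_ij / sqrt(theta_ii * theta_jj).

A covariate node (age) can be included in the estimation and dropped from
the reported network afterwards, so that every edge is conditioned on the
covariate without the covariate appearing in plots or centrality.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.linalg import pinvh
from sklearn.covariance import graphical_lasso as _sk_graphical_lasso

from .data import RatingMatrix
from .preprocessing import CorrelationEstimate, clean_scores, gaussianise, \
    pairwise_correlations, nearest_correlation_repair

__all__ = [
    "NetworkModel",
    "PipelineConfig",
    "lambda_path",
    "glasso_fit",
    "partial_corr_from_precision",
    "ebic_score",
    "select_model",
    "threshold_network",
    "drop_covariate_nodes",
    "fit_from_clean",
    "estimate_network",
]


@dataclass
class NetworkModel:
    """Estimated partial-correlation network."""

    nodes: list
    precision: np.ndarray
    adjacency: np.ndarray  # partial correlations, zero diagonal
    lambda_selected: float
    gamma: float
    path: list = field(default_factory=list)  # (lambda, edge_count, ebic)
    thresholded: bool = False
    tau: float = 0.0
    covariate_nodes: list = field(default_factory=list)
    adjacency_unthresholded: Optional[np.ndarray] = None
    effective_n: Optional[int] = None

    @property
    def p(self) -> int:
        return len(self.nodes)

    @property
    def edge_count(self) -> int:
        iu = np.triu_indices(self.p, k=1)
        return int(np.count_nonzero(self.adjacency[iu]))

    def weight(self, a, b) -> float:
        i, j = self.nodes.index(a), self.nodes.index(b)
        return float(self.adjacency[i, j])

    def edges(self) -> list:
        """Sorted (node_i, node_j, weight) triples for nonzero edges."""
        iu = np.triu_indices(self.p, k=1)
        out = []
        for i, j in zip(*iu):
            w = self.adjacency[i, j]
            if w != 0:
                out.append((self.nodes[i], self.nodes[j], float(w)))
        return out


@dataclass
class PipelineConfig:
    """Switches for the estimation variants.

    The default configuration is the headline analysis: nonparanormal
    transform, pairwise-complete correlations, glasso path with EBIC
    (gamma = 0.5), theoretical-bound thresholding, age included in
    estimation and dropped from the reported network.
    """

    transform: bool = True
    method: str = "pairwise"  # or "listwise"
    regularised: bool = True
    threshold: bool = True
    gamma: float = 0.5
    n_lambda: int = 100
    min_ratio: float = 0.01
    tau_override: Optional[float] = None
    include_age: bool = True
    z_cut: float = 3.5
    mahal_alpha: float = 0.001
    effective_n_mode: str = "rows"
    walktrap_steps: int = 4

    def __post_init__(self) -> None:
        if self.tau_override is not None and not self.threshold:
            raise ValueError("tau_override requires threshold=True")


def lambda_path(corr: CorrelationEstimate | np.ndarray, n_lambda: int = 100,
                min_ratio: float = 0.01) -> np.ndarray:
    """Log-spaced penalty grid on [min_ratio * lambda_max, lambda_max],
    lambda_max = max off-diagonal |correlation|."""
    S = corr.matrix if isinstance(corr, CorrelationEstimate) else np.asarray(corr)
    p = S.shape[0]
    iu = np.triu_indices(p, k=1)
    lam_max = float(np.abs(S[iu]).max())
    if lam_max == 0:
        raise ValueError("all off-diagonal correlations are zero; no path to search")
    return np.geomspace(min_ratio * lam_max, lam_max, num=n_lambda)


def glasso_fit(corr: CorrelationEstimate | np.ndarray, lam: float,
               tol: float = 1e-6, max_iter: int = 500) -> np.ndarray:
    """Precision matrix maximising the L1-penalised Gaussian
    log-likelihood (off-diagonal penalty only).  lam = 0 returns the
    (pseudo-)inverse of the input."""
    S = corr.matrix if isinstance(corr, CorrelationEstimate) else np.asarray(corr)
    if lam < 0:
        raise ValueError("penalty must be nonnegative")
    if lam == 0:
        return pinvh(S)
    _, precision = _sk_graphical_lasso(S, alpha=float(lam), tol=tol,
                                       enet_tol=1e-7, max_iter=max_iter)
    return precision


def partial_corr_from_precision(precision: np.ndarray) -> np.ndarray:
    """w_ij = -theta_ij / sqrt(theta_ii theta_jj), zero diagonal."""
    d = np.sqrt(np.diag(precision))
    W = -precision / np.outer(d, d)
    np.fill_diagonal(W, 0.0)
    return (W + W.T) / 2.0


def ebic_score(precision: np.ndarray, corr: CorrelationEstimate | np.ndarray,
               n: int, gamma: float = 0.5) -> float:
    """EBIC = -n [log det Theta - tr(S Theta)] + E log n + 4 E gamma log p,
    with E the number of nonzero upper-triangle off-diagonal entries."""
    S = corr.matrix if isinstance(corr, CorrelationEstimate) else np.asarray(corr)
    sign, logdet = np.linalg.slogdet(precision)
    if sign <= 0:
        raise ValueError("precision matrix is not positive definite")
    p = precision.shape[0]
    iu = np.triu_indices(p, k=1)
    E = int(np.count_nonzero(precision[iu]))
    loglik_term = logdet - float(np.trace(S @ precision))
    return -n * loglik_term + E * np.log(n) + 4.0 * E * gamma * np.log(p)


def select_model(corr: CorrelationEstimate, n: Optional[int] = None,
                 gamma: float = 0.5, path: Optional[Sequence[float]] = None,
                 covariate_nodes: Sequence[str] = ()) -> NetworkModel:
    """Fit the glasso at every penalty on the path and return the model
    minimising EBIC; ties break toward the larger penalty (sparser)."""
    if n is None:
        n = corr.effective_n
    if path is None:
        path = lambda_path(corr)
    path = np.asarray(list(path), dtype=float)
    if path.size == 0:
        raise ValueError("empty penalty path")

    records = []
    best = None
    S = corr.matrix
    p = S.shape[0]
    iu = np.triu_indices(p, k=1)
    for lam in path:
        try:
            prec = glasso_fit(corr, lam)
        except FloatingPointError as exc:  # pragma: no cover - degenerate input
            warnings.warn(f"glasso failed at lambda={lam:.4g}: {exc}")
            continue
        E = int(np.count_nonzero(prec[iu]))
        score = ebic_score(prec, S, n=n, gamma=gamma)
        records.append((float(lam), E, float(score)))
        # strict < keeps the earlier (larger-lambda) model on ties when we
        # iterate the path descending; iterate descending to realise that
        if best is None or score < best[0] or (score == best[0] and lam > best[1]):
            best = (score, float(lam), prec)
    if best is None:
        raise RuntimeError("glasso failed at every penalty on the path")
    _, lam_sel, prec_sel = best
    W = partial_corr_from_precision(prec_sel)
    return NetworkModel(nodes=list(corr.nodes), precision=prec_sel, adjacency=W,
                        lambda_selected=lam_sel, gamma=gamma, path=records,
                        covariate_nodes=list(covariate_nodes), effective_n=n)


def default_tau(p: int, n: int) -> float:
    """Theoretical sparsity bound tau = sqrt(log(p(p-1)/2) / n)."""
    return float(np.sqrt(np.log(p * (p - 1) / 2.0) / n))


def threshold_network(model: NetworkModel, n: Optional[int] = None,
                      tau: Optional[float] = None) -> NetworkModel:
    """Zero all edges with |w| < tau; keeps the unthresholded adjacency
    alongside for comparison."""
    if n is None:
        n = model.effective_n
    if tau is None:
        tau = default_tau(model.p, n)
    W = model.adjacency.copy()
    W[np.abs(W) < tau] = 0.0
    return replace(model, adjacency=W, thresholded=True, tau=float(tau),
                   adjacency_unthresholded=model.adjacency.copy())


def drop_covariate_nodes(model: NetworkModel) -> NetworkModel:
    """Induced submodel on the non-covariate nodes (no re-estimation)."""
    if not model.covariate_nodes:
        raise ValueError("model has no covariate nodes to drop")
    keep = [i for i, v in enumerate(model.nodes) if v not in model.covariate_nodes]
    if len(keep) < 3:
        raise ValueError("dropping covariates would leave fewer than 3 nodes")
    idx = np.ix_(keep, keep)
    return replace(
        model,
        nodes=[model.nodes[i] for i in keep],
        precision=model.precision[idx],
        adjacency=model.adjacency[idx],
        adjacency_unthresholded=(model.adjacency_unthresholded[idx]
                                 if model.adjacency_unthresholded is not None else None),
        covariate_nodes=[],
    )


def fit_from_clean(clean: RatingMatrix, config: Optional[PipelineConfig] = None,
                   return_intermediates: bool = False):
    """Estimation on already-cleaned (oriented, outlier-treated) data:
    transform -> correlations -> repair -> glasso/EBIC (or unregularised
    pseudo-inverse) -> optional threshold -> covariate drop.

    This is the portion that bootstrap replicates re-run in full.
    """
    if config is None:
        config = PipelineConfig()
    transformed = gaussianise(clean, transform=config.transform,
                              include_age=config.include_age)
    est = pairwise_correlations(transformed, method=config.method,
                                effective_n_mode=config.effective_n_mode)
    est = nearest_correlation_repair(est)

    covariates = ["age"] if (config.include_age and "age" in est.nodes) else []
    if config.regularised:
        grid = lambda_path(est, n_lambda=config.n_lambda, min_ratio=config.min_ratio)
        # descending order so EBIC ties resolve toward the sparser model
        model = select_model(est, gamma=config.gamma, path=grid[::-1],
                             covariate_nodes=covariates)
    else:
        prec = pinvh(est.matrix)
        model = NetworkModel(nodes=est.nodes, precision=prec,
                             adjacency=partial_corr_from_precision(prec),
                             lambda_selected=0.0, gamma=config.gamma,
                             covariate_nodes=covariates,
                             effective_n=est.effective_n)
    if config.threshold:
        model = threshold_network(model, tau=config.tau_override)
    full_model = model
    if covariates:
        model = drop_covariate_nodes(model)
    if return_intermediates:
        return model, transformed, est, full_model
    return model


def estimate_network(data: RatingMatrix, config: Optional[PipelineConfig] = None,
                     return_intermediates: bool = False):
    """End-to-end estimation from raw ratings: cleaning (orientation,
    outlier treatment) followed by :func:`fit_from_clean`.

    With ``return_intermediates`` returns ``(model, clean, transformed,
    correlation_estimate, full_model)`` where ``full_model`` still
    carries the covariate node.
    """
    if config is None:
        config = PipelineConfig()
    clean = clean_scores(data, z_cut=config.z_cut, mahal_alpha=config.mahal_alpha)
    if return_intermediates:
        model, transformed, est, full_model = fit_from_clean(
            clean, config, return_intermediates=True)
        return model, clean, transformed, est, full_model
    return fit_from_clean(clean, config)
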