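"""Preprocessing: orientation, outlier treatment, nonparanormal transform,
pairwise-complete correlation and positive-definiteness repair.

The fixed pipeline order is: orient -> univariate outliers to missing ->
multivariate outlier row removal -> nonparanormal transform + standardise
-> (pairwise or listwise) Pearson correlations -> nearest-correlation
repair.  Each step logs what it changed on the RatingMatrix.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from scipy import stats
from scipy.special import ndtri

from .data import RatingMatrix

__all__ = [
    "CorrelationEstimate",
    "orient_scores",
    "univariate_outlier_to_missing",
    "multivariate_outlier_removal",
    "nonparanormal_transform",
    "pairwise_correlations",
    "nearest_correlation_repair",
    "preprocess",
]


@dataclass
class CorrelationEstimate:
    """Correlation matrix plus bookkeeping needed downstream.

    ``effective_n`` is the sample size passed to EBIC and thresholding:
    under pairwise estimation it is the number of rows in the analysed
    table (the single-n convention of the common network workflow);
    ``mean pairwise n`` is available via ``effective_n_mode``.
    """

    corr: pd.DataFrame
    pairwise_n: pd.DataFrame
    method: str
    effective_n: int
    repaired: bool = False
    max_repair_delta: float = 0.0

    @property
    def nodes(self) -> list:
        return list(self.corr.columns)

    @property
    def matrix(self) -> np.ndarray:
        return self.corr.to_numpy()


def orient_scores(data: RatingMatrix) -> RatingMatrix:
    """Reflect difficulty-decreasing variables so every score increases
    with difficulty.

    With known bounds (lo, hi) a value x maps to hi - x; without bounds it
    is negated.  Missing cells stay missing, orientation flags end up all
    True.
    """
    out = data.copy()
    new_bounds = dict(out.bounds) if out.bounds is not None else None
    for name in out.variable_names:
        if bool(out.orientation[name]):
            continue
        if out.bounds is not None and name in out.bounds:
            lo, hi = out.bounds[name]
            out.values[name] = hi - out.values[name]
            new_bounds[name] = (hi - hi, hi - lo)
        else:
            out.values[name] = -out.values[name]
        out.orientation[name] = True
    out.bounds = new_bounds
    out.log.append({"step": "orient",
                    "reflected": int((~data.orientation).sum())})
    return out


def univariate_outlier_to_missing(
    data: RatingMatrix, z_cut: float = 3.5
) -> Tuple[RatingMatrix, int]:
    """Replace cells further than ``z_cut`` SDs from their variable mean
    with missing.

    Means and SDs are the missing-excluded per-variable statistics
    computed before any replacement; all replacements are simultaneous.
    Zero-SD variables are skipped with a warning.
    """
    if z_cut <= 0:
        raise ValueError("z_cut must be positive")
    out = data.copy()
    vals = out.values.to_numpy()
    mu = np.nanmean(vals, axis=0)
    sd = np.nanstd(vals, axis=0, ddof=1)
    count = 0
    cells = []
    for j, name in enumerate(out.variable_names):
        if sd[j] == 0 or np.isnan(sd[j]):
            warnings.warn(f"variable {name} has zero SD; outlier rule skipped")
            continue
        z = np.abs(vals[:, j] - mu[j]) / sd[j]
        hits = np.nonzero(z > z_cut)[0]
        for i in hits:
            vals[i, j] = np.nan
            cells.append((int(i), name))
        count += len(hits)
    out.values = pd.DataFrame(vals, index=out.values.index,
                              columns=out.values.columns)
    out.log.append({"step": "univariate_outliers", "replaced": count,
                    "cells": cells, "z_cut": z_cut})
    return out, count


def multivariate_outlier_removal(
    data: RatingMatrix, alpha: float = 0.001
) -> Tuple[RatingMatrix, list]:
    """Drop rows whose Mahalanobis D^2 exceeds the chi-square(p, 1-alpha)
    quantile.

    D^2 is computed on a mean-imputed copy (imputation is used for the
    distance only, never written back).  A singular covariance is
    ridge-repaired with 1e-6 * I.
    """
    p = data.p
    vals = data.values.to_numpy()
    complete = ~np.isnan(vals).any(axis=1)
    if complete.sum() < p + 2:
        raise ValueError("need at least p+2 complete rows for Mahalanobis screening")
    imputed = vals.copy()
    col_mean = np.nanmean(vals, axis=0)
    nan_r, nan_c = np.nonzero(np.isnan(imputed))
    imputed[nan_r, nan_c] = col_mean[nan_c]

    mu = imputed.mean(axis=0)
    S = np.cov(imputed, rowvar=False)
    try:
        S_inv = np.linalg.inv(S)
    except np.linalg.LinAlgError:
        warnings.warn("singular covariance in Mahalanobis screen; ridge-repaired")
        S_inv = np.linalg.inv(S + 1e-6 * np.eye(p))
    centred = imputed - mu
    d2 = np.einsum("ij,jk,ik->i", centred, S_inv, centred)

    if alpha <= 0:
        cutoff = np.inf
    else:
        cutoff = stats.chi2.ppf(1 - alpha, df=p)
    removed_mask = d2 > cutoff
    removed_ids = [data.row_ids[i] for i in np.nonzero(removed_mask)[0]]

    out = data.copy()
    keep = ~removed_mask
    out.values = out.values.loc[keep]
    if out.age is not None:
        out.age = out.age.loc[keep]
    if out.group is not None:
        out.group = out.group.loc[keep]
    out.log.append({"step": "multivariate_outliers", "removed": removed_ids,
                    "alpha": alpha, "cutoff": float(cutoff)})
    return out, removed_ids


def _winsorised_probit(col: np.ndarray) -> np.ndarray:
    """Nonparanormal marginal: midrank ECDF, winsorised, probit."""
    obs = ~np.isnan(col)
    m = int(obs.sum())
    x = col[obs]
    if np.nanstd(x) == 0:
        raise ValueError("constant variable")
    ranks = stats.rankdata(x, method="average")
    u = ranks / m
    delta = 1.0 / (4.0 * m ** 0.25 * np.sqrt(np.pi * np.log(m)))
    u = np.clip(u, delta, 1.0 - delta)
    out = np.full_like(col, np.nan)
    out[obs] = ndtri(u)
    return out


def nonparanormal_delta(m: int) -> float:
    """Winsorisation level delta_m = 1 / (4 m^{1/4} sqrt(pi log m))."""
    return 1.0 / (4.0 * m ** 0.25 * np.sqrt(np.pi * np.log(m)))


def nonparanormal_transform(data: RatingMatrix) -> RatingMatrix:
    """Gaussianise each variable by the winsorised-ECDF probit map, then
    centre and scale to unit sample SD.

    The map is rank-based, hence invariant to any strictly monotone
    marginal pre-transformation; ties share transformed values and
    missing cells stay missing.
    """
    out = data.copy()
    for name in out.variable_names:
        col = out.values[name].to_numpy()
        m = int((~np.isnan(col)).sum())
        if m < 10:
            raise ValueError(f"variable {name} has fewer than 10 observed values")
        try:
            z = _winsorised_probit(col)
        except ValueError:
            raise ValueError(f"variable {name} is constant; cannot transform")
        mu = np.nanmean(z)
        sd = np.nanstd(z, ddof=1)
        out.values[name] = (z - mu) / sd
    out.log.append({"step": "nonparanormal", "standardised": True})
    return out


def standardise(data: RatingMatrix) -> RatingMatrix:
    """Centre and scale every variable to unit sample SD (no rank map)."""
    out = data.copy()
    for name in out.variable_names:
        col = out.values[name]
        sd = col.std(ddof=1)
        if sd == 0 or np.isnan(sd):
            raise ValueError(f"variable {name} is constant; cannot standardise")
        out.values[name] = (col - col.mean()) / sd
    out.log.append({"step": "standardise"})
    return out


def pairwise_correlations(data: RatingMatrix, method: str = "pairwise",
                          min_pairs: int = 10,
                          effective_n_mode: str = "rows") -> CorrelationEstimate:
    """Pearson correlations over complete pairs (``pairwise``) or complete
    rows (``listwise``).

    Raises when any variable pair has fewer than ``min_pairs`` complete
    observations.  ``effective_n`` follows ``effective_n_mode``: "rows"
    (number of rows in the table; listwise: complete rows) or
    "mean_pairwise".
    """
    if method not in ("pairwise", "listwise"):
        raise ValueError(f"unknown method {method!r}")
    df = data.values
    obs = df.notna().to_numpy().astype(int)
    pair_n = pd.DataFrame(obs.T @ obs, index=df.columns, columns=df.columns)

    if method == "listwise":
        df_used = df.dropna(axis=0)
        if df_used.shape[0] < min_pairs:
            raise ValueError("fewer than min_pairs complete rows for listwise correlations")
        corr = df_used.corr()
        n_rows = df_used.shape[0]
        pair_n.loc[:, :] = n_rows
    else:
        off = pair_n.to_numpy()[np.triu_indices(data.p, k=1)]
        if off.min() < min_pairs:
            raise ValueError(
                f"a variable pair has only {int(off.min())} complete observations "
                f"(< {min_pairs})"
            )
        corr = df.corr(min_periods=min_pairs)
        n_rows = df.shape[0]

    if effective_n_mode == "rows":
        eff_n = int(n_rows)
    elif effective_n_mode == "mean_pairwise":
        eff_n = int(round(pair_n.to_numpy()[np.triu_indices(data.p, k=1)].mean()))
    else:
        raise ValueError(f"unknown effective_n_mode {effective_n_mode!r}")
    return CorrelationEstimate(corr=corr, pairwise_n=pair_n, method=method,
                               effective_n=eff_n)


def nearest_correlation_repair(est: CorrelationEstimate,
                               tol: float = 1e-8,
                               max_iter: int = 100) -> CorrelationEstimate:
    """Repair an indefinite correlation matrix by eigenvalue clipping.

    Iterates: clip negative eigenvalues to ``tol``, rebuild, renormalise
    the diagonal to 1; stops when the smallest eigenvalue is >= -tol.
    """
    A = est.matrix.copy()
    if not np.allclose(A, A.T, atol=1e-12):
        raise ValueError("correlation matrix must be symmetric")
    original = A.copy()
    repaired = False
    for _ in range(max_iter):
        w, V = np.linalg.eigh(A)
        if w[0] >= -tol:
            break
        repaired = True
        w = np.clip(w, tol, None)
        A = (V * w) @ V.T
        d = np.sqrt(np.diag(A))
        A = A / np.outer(d, d)
        A = (A + A.T) / 2.0
        np.fill_diagonal(A, 1.0)
    else:
        raise RuntimeError("nearest-correlation repair did not converge")
    delta = float(np.abs(A - original).max())
    corr = pd.DataFrame(A, index=est.corr.index, columns=est.corr.columns)
    return CorrelationEstimate(corr=corr, pairwise_n=est.pairwise_n,
                               method=est.method, effective_n=est.effective_n,
                               repaired=repaired, max_repair_delta=delta)


def clean_scores(data: RatingMatrix, z_cut: float = 3.5,
                 mahal_alpha: float = 0.001) -> RatingMatrix:
    """Cleaning chain only: orient, univariate outliers to missing,
    multivariate outlier row removal.  Returns data on the raw score
    scale; the transform happens at estimation time (and is re-run inside
    every bootstrap replicate)."""
    step = orient_scores(data)
    step, _ = univariate_outlier_to_missing(step, z_cut=z_cut)
    step, _ = multivariate_outlier_removal(step, alpha=mahal_alpha)
    return step


def gaussianise(data: RatingMatrix, transform: bool = True,
                include_age: bool = True) -> RatingMatrix:
    """Append age as an ordinary column (when requested), then apply the
    nonparanormal transform or plain standardisation."""
    step = data.copy()
    if include_age and step.age is not None:
        step.values = step.values.assign(age=step.age.to_numpy())
        step.orientation = pd.concat(
            [step.orientation, pd.Series({"age": True})]
        )
    return nonparanormal_transform(step) if transform else standardise(step)


def preprocess(data: RatingMatrix, z_cut: float = 3.5,
               mahal_alpha: float = 0.001, transform: bool = True,
               include_age: bool = True) -> RatingMatrix:
    """Full chain: orient -> univariate outliers -> multivariate outliers
    -> nonparanormal transform (or standardisation) with age appended as
    an ordinary column beforehand when requested."""
    step = clean_scores(data, z_cut=z_cut, mahal_alpha=mahal_alpha)
    return gaussianise(step, transform=transform, include_age=include_age)
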