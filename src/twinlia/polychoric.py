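"""Polychoric correlation from a K x K ordinal twin-pair table.

Under the liability-threshold model each margin of the cross-tabulated
pair scores is a standard-normal variable cut at thresholds tau, and
the cell (i, j) probability is the bivariate-normal measure of the
rectangle (tau_{i-1}, tau_i] x (tau_{j-1}, tau_j] at latent correlation
rho.  Estimation is the standard two-stage procedure: thresholds are
the normal quantiles of the cumulative marginal proportions, then rho
maximises the multinomial log-likelihood sum(n_ij * log p_ij) in one
dimension.  The standard error comes from the curvature of the profile
log-likelihood at the optimum.

Because twins within a pair are interchangeable, tables are built by
double entry — each pair contributes (s1, s2) and (s2, s1) — which
symmetrises the table; standard errors are computed on the effective
number of pairs, not the doubled count.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import optimize
from scipy.stats import multivariate_normal, norm
from sklearn.base import BaseEstimator

logger = logging.getLogger(__name__)

_RHO_BOUND = 0.999
_CELL_FLOOR = 1e-30


@dataclass(frozen=True)
class PolychoricEstimate:
    """Fitted latent correlation and thresholds for one zygosity group."""

    rho: float
    tau_rows: np.ndarray
    tau_cols: np.ndarray
    se_rho: float
    loglik: float
    n_pairs: int
    zygosity: Optional[str] = None
    at_boundary: bool = False


def bivariate_normal_cdf(h, k, rho: float) -> np.ndarray:
    """Standard bivariate normal P(X <= h, Y <= k); handles +-inf limits."""
    h = np.atleast_1d(np.asarray(h, dtype=float))
    k = np.atleast_1d(np.asarray(k, dtype=float))
    h, k = np.broadcast_arrays(h, k)
    out = np.empty(h.shape)
    neg_inf = (h == -np.inf) | (k == -np.inf)
    h_inf, k_inf = h == np.inf, k == np.inf
    out[neg_inf] = 0.0
    out[h_inf & ~neg_inf] = norm.cdf(k[h_inf & ~neg_inf])
    out[k_inf & ~neg_inf & ~h_inf] = norm.cdf(h[k_inf & ~neg_inf & ~h_inf])
    interior = ~(neg_inf | h_inf | k_inf)
    if interior.any():
        pts = np.column_stack([h[interior], k[interior]])
        cov = np.array([[1.0, rho], [rho, 1.0]])
        out[interior] = multivariate_normal.cdf(
            pts, mean=np.zeros(2), cov=cov, abseps=1e-8, releps=0.0
        )
    return out


def cell_probabilities(tau_rows, tau_cols, rho: float) -> np.ndarray:
    """K x K table of bivariate-normal rectangle probabilities.

    Entry (i, j) is the probability mass of liability rectangle
    (tau_{i-1}, tau_i] x (tau_{j-1}, tau_j] with tau_0 = -inf and
    tau_K = +inf; entries sum to 1.
    """
    tau_rows = np.asarray(tau_rows, dtype=float)
    tau_cols = np.asarray(tau_cols, dtype=float)
    for tau in (tau_rows, tau_cols):
        if tau.size and np.any(np.diff(tau) <= 0):
            raise ValueError("thresholds must be strictly increasing")
    if not abs(rho) < 1:
        raise ValueError("rho must lie in (-1, 1)")
    a = np.concatenate([[-np.inf], tau_rows, [np.inf]])
    b = np.concatenate([[-np.inf], tau_cols, [np.inf]])
    hh, kk = np.meshgrid(a, b, indexing="ij")
    cum = bivariate_normal_cdf(hh.ravel(), kk.ravel(), rho).reshape(hh.shape)
    cells = np.diff(np.diff(cum, axis=0), axis=1)
    return np.clip(cells, 0.0, 1.0)


def estimate_thresholds(marginal_counts) -> np.ndarray:
    """Thresholds as normal quantiles of cumulative marginal proportions."""
    counts = np.asarray(marginal_counts, dtype=float)
    if counts.sum() <= 0:
        raise ValueError("marginal counts must have a positive total")
    cum = np.cumsum(counts)[:-1] / counts.sum()
    if np.any(cum <= 0) or np.any(cum >= 1):
        raise ValueError(
            "an interior cumulative proportion is 0 or 1; collapse the empty "
            "category with its neighbour before estimating thresholds"
        )
    return norm.ppf(cum)


def double_enter(records, zygosity: str, n_categories: int = 4) -> np.ndarray:
    """Symmetrised contingency table for one zygosity group.

    Each pair is entered at (score1, score2) and (score2, score1), so
    the table equals its transpose and totals twice the pair count.
    """
    sub = records[records["zygosity"] == zygosity]
    if len(sub) == 0:
        raise ValueError(f"no records with zygosity {zygosity!r}")
    s1 = sub["score1"].to_numpy(int)
    s2 = sub["score2"].to_numpy(int)
    if s1.min() < 0 or s2.min() < 0 or max(s1.max(), s2.max()) >= n_categories:
        raise ValueError(f"scores out of range 0..{n_categories - 1}")
    counts = np.zeros((n_categories, n_categories), dtype=int)
    np.add.at(counts, (s1, s2), 1)
    np.add.at(counts, (s2, s1), 1)
    return counts


def _collapse_empty(counts: np.ndarray) -> np.ndarray:
    """Drop categories with empty row AND column margins (logged)."""
    row_keep = counts.sum(axis=1) > 0
    col_keep = counts.sum(axis=0) > 0
    if not row_keep.all() or not col_keep.all():
        logger.warning(
            "collapsing %d empty row / %d empty column categories",
            (~row_keep).sum(), (~col_keep).sum(),
        )
    return counts[np.ix_(row_keep, col_keep)]


def fit_polychoric(
    table: np.ndarray,
    zygosity: Optional[str] = None,
    n_pairs: Optional[int] = None,
    collapse_empty: bool = True,
) -> PolychoricEstimate:
    """Two-stage maximum-likelihood polychoric estimate from a count table.

    Parameters
    ----------
    table : (K, K) array of non-negative counts (rows twin 1, cols twin 2).
    n_pairs : effective number of independent pairs.  For a double-entered
        table pass the pair count (= total/2); the standard error is then
        computed on that effective sample size.  Defaults to the table
        total (independent observations).
    """
    counts = np.asarray(table, dtype=float)
    if counts.ndim != 2 or np.any(counts < 0) or counts.sum() <= 0:
        raise ValueError("table must be a non-negative count matrix with positive total")
    if collapse_empty:
        counts = _collapse_empty(counts)
    if min(counts.shape) < 2 or (counts.sum(axis=1) > 0).sum() < 2 or (
        counts.sum(axis=0) > 0
    ).sum() < 2:
        raise ValueError("need at least two non-empty categories per margin")
    total = counts.sum()
    n_eff = int(n_pairs) if n_pairs is not None else int(round(total))
    tau_r = estimate_thresholds(counts.sum(axis=1))
    tau_c = estimate_thresholds(counts.sum(axis=0))

    def negloglik(rho: float) -> float:
        p = np.clip(cell_probabilities(tau_r, tau_c, rho), _CELL_FLOOR, 1.0)
        return -float((counts * np.log(p)).sum())

    res = optimize.minimize_scalar(
        negloglik, bounds=(-_RHO_BOUND, _RHO_BOUND), method="bounded",
        options={"xatol": 1e-6},
    )
    rho = float(res.x)
    at_boundary = abs(rho) >= _RHO_BOUND - 1e-4
    if at_boundary:
        rho = float(np.sign(rho) * _RHO_BOUND)
        warnings.warn("polychoric estimate at the boundary; clamped to +-0.999")
    # observed information from the profile log-likelihood curvature,
    # rescaled from the table total to the effective sample size
    h = 1e-4
    r0 = np.clip(rho, -_RHO_BOUND + 2 * h, _RHO_BOUND - 2 * h)
    d2 = (negloglik(r0 + h) - 2 * negloglik(r0) + negloglik(r0 - h)) / h**2
    info = d2 * (n_eff / total)
    se = float(1.0 / np.sqrt(info)) if info > 0 else float("inf")
    return PolychoricEstimate(
        rho=rho,
        tau_rows=tau_r,
        tau_cols=tau_c,
        se_rho=se,
        loglik=-res.fun,
        n_pairs=n_eff,
        zygosity=zygosity,
        at_boundary=at_boundary,
    )


class PolychoricCorrelation(BaseEstimator):
    """Scikit-learn-style estimator of the latent pair correlation.

    ``fit`` accepts an (n, 2) integer array of paired ordinal scores
    (one row per twin pair).  With ``double_entry=True`` (default) the
    table is symmetrised before estimation, reflecting twin
    interchangeability, and the standard error uses the pair count.

    Attributes (after :meth:`fit`)
    ------------------------------
    rho_, se_rho_ : latent correlation and its standard error
    tau_rows_, tau_cols_ : estimated thresholds
    loglik_, table_, n_pairs_, at_boundary_
    """

    def __init__(self, n_categories: int = 4, double_entry: bool = True):
        self.n_categories = n_categories
        self.double_entry = double_entry

    def fit(self, X, y=None):
        X = np.asarray(X)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ValueError("X must be an (n_pairs, 2) array of ordinal scores")
        if not np.issubdtype(X.dtype, np.integer):
            if not np.allclose(X, np.round(X)):
                raise ValueError("scores must be integers")
            X = X.astype(int)
        if X.min() < 0 or X.max() >= self.n_categories:
            raise ValueError(f"scores out of range 0..{self.n_categories - 1}")
        k = self.n_categories
        counts = np.zeros((k, k), dtype=int)
        np.add.at(counts, (X[:, 0], X[:, 1]), 1)
        if self.double_entry:
            np.add.at(counts, (X[:, 1], X[:, 0]), 1)
        est = fit_polychoric(counts, n_pairs=len(X))
        self.estimate_ = est
        self.rho_ = est.rho
        self.se_rho_ = est.se_rho
        self.tau_rows_ = est.tau_rows
        self.tau_cols_ = est.tau_cols
        self.loglik_ = est.loglik
        self.table_ = counts
        self.n_pairs_ = est.n_pairs
        self.at_boundary_ = est.at_boundary
        return self
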