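"""Functional connectivity: Pearson correlation, power-law-optimal
thresholding, binarization and degrees.

The connectivity of ROI i is its degree — the number of other ROIs j whose
Pearson correlation rho_ij exceeds a threshold tau.  Because the choice of
tau strongly biases network properties, tau is selected per subject by
scanning a grid and, at each candidate, fitting the binarized network's
degree distribution P(k) to a power law P(k) ~ k^(-gamma) by ordinary least
squares on the log10-log10 scale; the tau maximizing the coefficient of
determination r^2 is the optimum (scale-free/small-world organization is
the selection principle).  A non-thresholded variant sums the signed
correlation values per ROI instead.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .signal_io import SignalMatrix

logger = logging.getLogger(__name__)

#: Default threshold grid: 0.05 .. 0.95 in steps of 0.05.  Spans the optima
#: typically seen for calcium (0.4-0.6) and BOLD (~0.7) data.
DEFAULT_TAU_GRID = np.round(np.arange(0.05, 0.951, 0.05), 10)

#: Minimum number of occupied degree bins for a log-log fit to be defined.
MIN_POWERLAW_BINS = 3


@dataclass
class CorrelationMatrix:
    """Pearson correlation matrix of the ROI time series.

    Zero-variance ROIs cannot be correlated; their rows/columns are zeroed
    off-diagonal and flagged in ``zero_variance_flags``.
    """

    roi_ids: list[str]
    rho: np.ndarray
    zero_variance_flags: np.ndarray

    def __post_init__(self) -> None:
        self.rho = np.asarray(self.rho, dtype=float)
        self.zero_variance_flags = np.asarray(self.zero_variance_flags,
                                              dtype=bool)
        r = len(self.roi_ids)
        if self.rho.shape != (r, r):
            raise ValueError("rho must be square, matching roi_ids")


@dataclass
class ThresholdScan:
    """Power-law fit quality across the threshold grid.

    ``r2[k]`` is NaN where the fit is undefined (fewer than
    ``MIN_POWERLAW_BINS`` occupied degree bins); ``tau_optimal`` maximizes
    the defined r^2 values (ties -> smallest tau); ``gamma_hat`` is the
    fitted power-law exponent at the optimum.
    """

    tau_grid: np.ndarray
    r2: np.ndarray
    n_bins: np.ndarray
    gamma: np.ndarray
    tau_optimal: float
    gamma_hat: float

    @property
    def r2_optimal(self) -> float:
        return float(np.nanmax(self.r2))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"tau": self.tau_grid, "r2": self.r2,
                             "n_bins": self.n_bins, "gamma_hat": self.gamma})


@dataclass
class ConnectivityProfile:
    """Per-ROI connectivity (degrees or weighted correlation sums)."""

    roi_ids: list[str]
    degrees: np.ndarray
    method: str  # "thresholded" | "weighted_sum"
    tau: float | None = None
    adjacency: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.degrees = np.asarray(self.degrees, dtype=float)
        if len(self.degrees) != len(self.roi_ids):
            raise ValueError("degrees length must match roi_ids")


# ----------------------------------------------------------------------

def correlation_matrix(m: SignalMatrix) -> CorrelationMatrix:
    """Pearson correlation rho_ij = cov(i, j) / (sigma_i sigma_j).

    Diagonal is exactly 1; entries clipped to [-1, 1]; zero-variance rows
    are flagged and zeroed off-diagonal rather than raising.
    """
    if m.n_samples < 3:
        raise ValueError("need at least 3 time samples for correlation")
    flags = m.values.std(axis=1) == 0
    with np.errstate(invalid="ignore", divide="ignore"):
        rho = np.corrcoef(m.values)
    rho = np.asarray(rho, dtype=float)
    rho[flags, :] = 0.0
    rho[:, flags] = 0.0
    rho = np.clip((rho + rho.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(rho, 1.0)
    if flags.any():
        logger.warning("correlation_matrix: %d zero-variance ROI(s) flagged",
                       int(flags.sum()))
    return CorrelationMatrix(roi_ids=list(m.roi_ids), rho=rho,
                             zero_variance_flags=flags)


def threshold_binarize(c: CorrelationMatrix, tau: float) -> np.ndarray:
    """Boolean adjacency: edge iff rho_ij > tau (strict), i != j.

    Negative correlations never form edges (tau > 0 and the comparison is
    on the signed value).
    """
    if not 0 < tau < 1:
        raise ValueError(f"tau must be in (0, 1), got {tau}")
    adj = c.rho > tau
    np.fill_diagonal(adj, False)
    return adj


def degrees(adjacency: np.ndarray) -> np.ndarray:
    """Degree_i = number of edges at ROI i (row sums of the adjacency)."""
    adj = np.asarray(adjacency, dtype=bool)
    if adj.ndim != 2 or adj.shape[0] != adj.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(adj, adj.T):
        raise ValueError("adjacency must be symmetric")
    if adj.diagonal().any():
        raise ValueError("adjacency must have a zero diagonal")
    return adj.sum(axis=1).astype(int)


def degree_distribution(deg) -> dict[int, float]:
    """P(k) = n_k / n over the observed degrees k."""
    deg = np.asarray(deg, dtype=int).ravel()
    if np.any(deg < 0):
        raise ValueError("degrees must be non-negative")
    ks, counts = np.unique(deg, return_counts=True)
    n = deg.size
    return {int(k): float(cnt) / n for k, cnt in zip(ks, counts)}


def powerlaw_r2(dist: dict[int, float]) -> tuple[float, float] | None:
    """OLS fit of log10 P(k) on log10 k; returns (r2, gamma_hat) or None.

    Only bins with k >= 1 and P(k) > 0 enter the fit (log of zero-degree
    bins is undefined).  With fewer than ``MIN_POWERLAW_BINS`` usable bins
    the fit is undefined and None is returned.  ``gamma_hat`` is the negated
    slope; a flat distribution fits exactly (r2 = 1) with gamma_hat = 0.
    """
    ks = np.array(sorted(k for k, p in dist.items() if k >= 1 and p > 0))
    if ks.size < MIN_POWERLAW_BINS:
        return None
    x = np.log10(ks.astype(float))
    y = np.log10(np.array([dist[int(k)] for k in ks]))
    A = np.column_stack([x, np.ones_like(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    resid = y - A @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(((y - y.mean()) ** 2).sum())
    if ss_tot == 0.0:
        r2 = 1.0  # constant y: the flat OLS line is an exact fit
    else:
        r2 = 1.0 - ss_res / ss_tot
    return float(r2), float(-coef[0])


def _usable_bins(dist: dict[int, float]) -> int:
    return sum(1 for k, p in dist.items() if k >= 1 and p > 0)


def optimal_threshold(c: CorrelationMatrix,
                      tau_grid=None) -> ThresholdScan:
    """Scan the tau grid and select the power-law-optimal threshold.

    For each tau: binarize, compute degrees and their distribution, fit the
    log-log power law.  ``tau_optimal`` is the argmax of the defined r^2
    values (ties -> smallest tau).  Raises if no tau yields a defined fit.
    """
    grid = DEFAULT_TAU_GRID if tau_grid is None else \
        np.asarray(tau_grid, dtype=float).ravel()
    if grid.size == 0 or np.any(grid <= 0) or np.any(grid >= 1):
        raise ValueError("tau grid values must lie in (0, 1)")
    if np.any(np.diff(grid) <= 0):
        raise ValueError("tau grid must be strictly increasing")

    r2 = np.full(grid.size, np.nan)
    gamma = np.full(grid.size, np.nan)
    n_bins = np.zeros(grid.size, dtype=int)
    for i, tau in enumerate(grid):
        dist = degree_distribution(degrees(threshold_binarize(c, tau)))
        n_bins[i] = _usable_bins(dist)
        fit = powerlaw_r2(dist)
        if fit is not None:
            r2[i], gamma[i] = fit

    if np.all(np.isnan(r2)):
        raise ValueError(
            "no threshold in the grid yields a defined power-law fit "
            f"(every tau has < {MIN_POWERLAW_BINS} occupied degree bins); "
            "widen the tau grid or check the data")
    best = int(np.nanargmax(r2))  # first maximum: smallest tau on ties
    gamma_hat = float(gamma[best])
    if gamma_hat <= 0:
        logger.warning("optimal_threshold: fitted exponent gamma_hat=%.3f "
                       "<= 0 at tau=%.3f; degree distribution is not "
                       "decreasing", gamma_hat, grid[best])
    return ThresholdScan(tau_grid=grid, r2=r2, n_bins=n_bins, gamma=gamma,
                         tau_optimal=float(grid[best]), gamma_hat=gamma_hat)


def thresholded_profile(c: CorrelationMatrix,
                        tau: float) -> ConnectivityProfile:
    """Binarize at tau and return the degree profile with its adjacency."""
    adj = threshold_binarize(c, tau)
    return ConnectivityProfile(roi_ids=list(c.roi_ids), degrees=degrees(adj),
                               method="thresholded", tau=float(tau),
                               adjacency=adj)


def weighted_degree(c: CorrelationMatrix,
                    mode: str = "signed") -> ConnectivityProfile:
    """Non-thresholded connectivity: per-ROI sum of correlation values.

    ``mode`` selects how off-diagonal correlations are summed: ``"signed"``
    (raw values, the default), ``"absolute"`` or ``"positive"`` (negative
    values clipped to zero).
    """
    w = c.rho.copy()
    np.fill_diagonal(w, 0.0)
    if mode == "absolute":
        w = np.abs(w)
    elif mode == "positive":
        w = np.clip(w, 0.0, None)
    elif mode != "signed":
        raise ValueError(f"unknown mode {mode!r}")
    return ConnectivityProfile(roi_ids=list(c.roi_ids), degrees=w.sum(axis=1),
                               method="weighted_sum", tau=None)


def edge_list(c: CorrelationMatrix, adjacency: np.ndarray) -> pd.DataFrame:
    """Upper-triangle edge list (roi_id_a, roi_id_b, rho) of an adjacency."""
    ii, jj = np.nonzero(np.triu(np.asarray(adjacency, dtype=bool), k=1))
    return pd.DataFrame({
        "roi_id_a": [c.roi_ids[i] for i in ii],
        "roi_id_b": [c.roi_ids[j] for j in jj],
        "rho": c.rho[ii, jj],
    })
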