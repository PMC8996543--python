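"""Exact one-dimensional k-means level classification.

Activity values (or connection degrees) are partitioned into k ordered
levels by minimizing the within-cluster sum of squared deviations.  In one
dimension the optimal clusters are contiguous in sorted order, so the global
optimum is found by dynamic programming over sorted-contiguous partitions —
no random initialization, hence fully deterministic.  Clusters are then
numbered by descending centroid: level 1 = "high", level k = "low".
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

logger = logging.getLogger(__name__)


@dataclass
class LevelAssignment:
    """Result of 1-D k-means classification.

    ``level[i]`` is in {1..k} with 1 the highest-centroid cluster;
    ``centroids`` are sorted descending; ``within_cluster_ss`` is the
    globally minimal sum of squared deviations.  ``k`` is the effective
    number of clusters (reduced from ``requested_k`` when the input has
    fewer distinct values).
    """

    roi_ids: list[str]
    level: np.ndarray
    k: int
    centroids: np.ndarray
    within_cluster_ss: float
    requested_k: int

    def __post_init__(self) -> None:
        self.level = np.asarray(self.level, dtype=int)
        self.centroids = np.asarray(self.centroids, dtype=float)
        if len(self.level) != len(self.roi_ids):
            raise ValueError("level length must match roi_ids")
        if self.level.min() < 1 or self.level.max() > self.k:
            raise ValueError("levels must lie in {1..k}")


def _segment_cost(s1: np.ndarray, s2: np.ndarray, j, i):
    """Sum of squared deviations of sorted segment x[j..i] (inclusive)."""
    cnt = i - j + 1
    s = s1[i + 1] - s1[j]
    ss = s2[i + 1] - s2[j]
    return ss - s * s / cnt


def kmeans_levels(values, k: int = 3, roi_ids=None) -> LevelAssignment:
    """Globally optimal 1-D k-means partition into ordered levels.

    Dynamic programming over split points of the sorted values (O(k n^2));
    ties in the optimum are broken toward the smallest split index, and
    groups of identical values straddling a boundary are moved wholly to
    one side (the side with lower total cost; remaining ties toward the
    higher level).  If the input has fewer than k distinct values, k is
    reduced accordingly and recorded.
    """
    x = np.asarray(values, dtype=float).ravel()
    n = x.size
    if not np.all(np.isfinite(x)):
        raise ValueError("values must be finite")
    if k < 1:
        raise ValueError("k must be >= 1")
    if n < k:
        raise ValueError(f"need at least k={k} values, got {n}")
    if roi_ids is None:
        roi_ids = [f"roi_{i + 1:04d}" for i in range(n)]
    roi_ids = list(roi_ids)
    if len(roi_ids) != n:
        raise ValueError("roi_ids length must match values")

    n_distinct = np.unique(x).size
    k_eff = min(k, n_distinct)
    if k_eff < k:
        logger.info("kmeans_levels: only %d distinct values, reducing "
                    "k from %d to %d", n_distinct, k, k_eff)

    order = np.argsort(x, kind="stable")
    xs = x[order]
    s1 = np.concatenate(([0.0], np.cumsum(xs)))
    s2 = np.concatenate(([0.0], np.cumsum(xs * xs)))

    idx = np.arange(n)
    D = np.empty((k_eff, n))
    B = np.zeros((k_eff, n), dtype=int)
    D[0] = _segment_cost(s1, s2, 0, idx)
    for m in range(1, k_eff):
        for i in range(m, n):
            j = np.arange(m, i + 1)
            tot = D[m - 1][j - 1] + _segment_cost(s1, s2, j, i)
            a = int(np.argmin(tot))  # first minimum: smallest split
            D[m, i] = tot[a]
            B[m, i] = m + a

    # backtrack cluster start indices (ascending clusters)
    starts = [0] * k_eff
    i = n - 1
    for m in range(k_eff - 1, 0, -1):
        starts[m] = int(B[m, i])
        i = starts[m] - 1

    bounds = starts + [n]
    # identical values straddling a boundary: move the whole tied run to the
    # side with lower total cost; exact cost ties go right (higher level)
    for m in range(1, k_eff):
        b = bounds[m]
        if xs[b - 1] != xs[b]:
            continue
        v = xs[b]
        lo = int(np.searchsorted(xs, v, side="left"))
        hi = int(np.searchsorted(xs, v, side="right"))
        candidates = [c for c in (lo, hi)
                      if bounds[m - 1] < c < bounds[m + 1]]
        if not candidates:
            continue

        def total_cost(bnd):
            return sum(_segment_cost(s1, s2, bnd[t], bnd[t + 1] - 1)
                       for t in range(k_eff))
        best_b, best_c = b, total_cost(bounds)
        for c in candidates:
            trial = list(bounds)
            trial[m] = c
            cost = total_cost(trial)
            # prefer strictly lower cost; on a tie prefer the smaller start
            # (run joins the right/higher-value cluster -> higher level)
            if cost < best_c - 1e-12 or (abs(cost - best_c) <= 1e-12
                                         and c < best_b):
                best_b, best_c = c, cost
        bounds[m] = best_b

    means = np.array([xs[bounds[t]:bounds[t + 1]].mean()
                      for t in range(k_eff)])
    wss = float(sum(_segment_cost(s1, s2, bounds[t], bounds[t + 1] - 1)
                    for t in range(k_eff)))

    # ascending cluster t -> level k_eff - t (level 1 = largest centroid)
    level_sorted = np.empty(n, dtype=int)
    for t in range(k_eff):
        level_sorted[bounds[t]:bounds[t + 1]] = k_eff - t
    level = np.empty(n, dtype=int)
    level[order] = level_sorted

    return LevelAssignment(roi_ids=roi_ids, level=level, k=k_eff,
                           centroids=means[::-1].copy(),
                           within_cluster_ss=max(wss, 0.0), requested_k=k)


def level_fractions(a: LevelAssignment) -> np.ndarray:
    """Fraction of ROIs in each level 1..k; sums to 1."""
    counts = np.bincount(a.level, minlength=a.k + 1)[1:a.k + 1]
    return counts / len(a.level)
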