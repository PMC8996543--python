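"""Cohort-level statistics: joint activity x connectivity level tables,
subject bootstraps, and activity-sorted connectivity curves.

The headline statistic is the fraction of ROIs falling in each
(activity level, connectivity level) cell; mutual exclusivity of high
activity and high connectivity shows up as an empty (AL-1, CL-1) cell.
Uncertainty across subjects is quantified with a percentile bootstrap
(subjects resampled with replacement).  The per-subject activity-sorted
degree curve is smoothed with locally weighted regression (LOWESS).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess as _sm_lowess

from .activity import ActivityProfile
from .connectivity import ConnectivityProfile
from .levels import LevelAssignment

logger = logging.getLogger(__name__)


@dataclass
class JointLevelTable:
    """Fractions of ROIs per (activity level, connectivity level) cell.

    ``fraction[a-1, c-1]`` is the fraction of ROIs with AL = a and CL = c;
    entries are >= 0 and sum to 1.
    """

    k_activity: int
    k_connectivity: int
    fraction: np.ndarray
    subject_id: str = ""

    def __post_init__(self) -> None:
        self.fraction = np.asarray(self.fraction, dtype=float)
        if self.fraction.shape != (self.k_activity, self.k_connectivity):
            raise ValueError("fraction shape must be k_activity x "
                             "k_connectivity")
        if np.any(self.fraction < 0):
            raise ValueError("fractions must be non-negative")
        if abs(self.fraction.sum() - 1.0) > 1e-12:
            raise ValueError("fractions must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.fraction,
            index=[f"AL-{a + 1}" for a in range(self.k_activity)],
            columns=[f"CL-{c + 1}" for c in range(self.k_connectivity)])


@dataclass
class BootstrapBands:
    """Elementwise percentile bands over bootstrap iterations."""

    mean: np.ndarray
    lo: np.ndarray   # 2.5 percentile
    hi: np.ndarray   # 97.5 percentile
    iterations: int
    seed: int


@dataclass
class RelationshipCurve:
    """Degrees of ROIs ordered by ascending activity, with a LOWESS fit."""

    subject_id: str
    x: np.ndarray          # activity rank order 1..R
    y: np.ndarray          # degree in that order
    y_smooth: np.ndarray   # locally weighted fit at each rank
    activity: np.ndarray   # sorted activity values (ascending)


@dataclass
class CurveBands:
    """Bootstrap bands of the smoothed curves on a common rank grid."""

    grid: np.ndarray       # normalized rank in [0, 1]
    mean: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    iterations: int
    seed: int
    monotone_fraction: float  # fraction of grid steps with non-increasing mean


# ----------------------------------------------------------------------

def joint_level_fractions(al: LevelAssignment, cl: LevelAssignment,
                          k_activity: int | None = None,
                          k_connectivity: int | None = None,
                          subject_id: str = "") -> JointLevelTable:
    """Cross-tabulate activity and connectivity levels into fractions.

    ``k_activity``/``k_connectivity`` default to the assignments' effective
    k but may be forced larger (padding empty rows/columns) so that tables
    remain shape-homogeneous across subjects when a degenerate subject
    collapsed to fewer levels.
    """
    if list(al.roi_ids) != list(cl.roi_ids):
        raise ValueError("activity and connectivity assignments must cover "
                         "the same ROIs in the same order")
    ka = al.k if k_activity is None else int(k_activity)
    kc = cl.k if k_connectivity is None else int(k_connectivity)
    if ka < al.k or kc < cl.k:
        raise ValueError("requested table shape smaller than the levels")
    n = len(al.level)
    frac = np.zeros((ka, kc))
    np.add.at(frac, (al.level - 1, cl.level - 1), 1.0 / n)
    return JointLevelTable(k_activity=ka, k_connectivity=kc, fraction=frac,
                           subject_id=subject_id)


def bootstrap_joint_distribution(tables: list[JointLevelTable],
                                 iterations: int = 25,
                                 seed: int = 0) -> BootstrapBands:
    """Percentile bootstrap of the cohort-mean joint table.

    Each iteration resamples the subjects with replacement (cohort size
    preserved) and averages their tables; bands are the elementwise
    2.5/97.5 percentiles over iterations and ``mean`` the across-iteration
    mean.
    """
    if not tables:
        raise ValueError("need at least one subject table")
    shape = tables[0].fraction.shape
    if any(t.fraction.shape != shape for t in tables):
        raise ValueError("subject tables must share one (k_a, k_c) shape")
    if len(tables) == 1:
        logger.warning("bootstrap over a single subject: bands degenerate "
                       "to that subject's table")
    if iterations == 1:
        logger.warning("iterations=1: lo == hi (single draw)")
    elif iterations < 100:
        logger.info("bootstrap with %d iterations; percentile bands are "
                    "coarse below ~100", iterations)
    rng = np.random.default_rng(seed)
    stack = np.stack([t.fraction for t in tables])
    n_sub = len(tables)
    draws = np.empty((iterations,) + shape)
    for it in range(iterations):
        idx = rng.integers(0, n_sub, size=n_sub)
        draws[it] = stack[idx].mean(axis=0)
    return BootstrapBands(mean=draws.mean(axis=0),
                          lo=np.percentile(draws, 2.5, axis=0),
                          hi=np.percentile(draws, 97.5, axis=0),
                          iterations=iterations, seed=seed)


def relationship_curve(activity: ActivityProfile, conn: ConnectivityProfile,
                       frac: float = 0.3, robust_iters: int = 0,
                       subject_id: str = "") -> RelationshipCurve:
    """Degrees sorted by ascending activity, LOWESS-smoothed over rank.

    The smoother uses tricube weights over a window spanning ``frac`` of
    the points, with ``robust_iters`` robustifying reweighting passes.
    With fewer than 10 ROIs smoothing is skipped (y_smooth = y).
    """
    if list(activity.roi_ids) != list(conn.roi_ids):
        raise ValueError("activity and connectivity profiles must cover "
                         "the same ROIs in the same order")
    if not 0 < frac <= 1:
        raise ValueError(f"frac must be in (0, 1], got {frac}")
    order = np.argsort(activity.activity, kind="stable")
    y = conn.degrees[order].astype(float)
    x = np.arange(1, len(y) + 1, dtype=float)
    if len(y) < 10:
        logger.warning("relationship_curve: fewer than 10 ROIs, smoothing "
                       "skipped")
        y_smooth = y.copy()
    else:
        y_smooth = _sm_lowess(y, x, frac=frac, it=robust_iters, xvals=x)
    return RelationshipCurve(subject_id=subject_id, x=x, y=y,
                             y_smooth=np.asarray(y_smooth, dtype=float),
                             activity=activity.activity[order])


def bootstrap_relationship(curves: list[RelationshipCurve],
                           iterations: int = 7, seed: int = 0,
                           grid_size: int = 101) -> CurveBands:
    """Bootstrap bands of the smoothed curves across subjects.

    Subjects may have different ROI counts, so each smoothed curve is
    linearly interpolated onto a common normalized-rank grid [0, 1] before
    resampling.  The ``monotone_fraction`` summarizes how much of the mean
    curve is non-increasing (1.0 = monotonically decreasing relationship).
    """
    if not curves:
        raise ValueError("need at least one curve")
    grid = np.linspace(0.0, 1.0, grid_size)
    interp = np.stack([
        np.interp(grid, (c.x - 1) / max(len(c.x) - 1, 1), c.y_smooth)
        for c in curves])
    rng = np.random.default_rng(seed)
    n_sub = len(curves)
    draws = np.empty((iterations, grid_size))
    for it in range(iterations):
        idx = rng.integers(0, n_sub, size=n_sub)
        draws[it] = interp[idx].mean(axis=0)
    mean = draws.mean(axis=0)
    mono = float(np.mean(np.diff(mean) <= 0.0))
    return CurveBands(grid=grid, mean=mean,
                      lo=np.percentile(draws, 2.5, axis=0),
                      hi=np.percentile(draws, 97.5, axis=0),
                      iterations=iterations, seed=seed,
                      monotone_fraction=mono)


def exclusivity_statistic(tables: list[JointLevelTable]) -> float:
    """Cohort-mean percentage of ROIs that are both AL-1 and CL-1.

    Zero means high activity and high connectivity are mutually exclusive.
    """
    if not tables:
        raise ValueError("need at least one subject table")
    return float(np.mean([t.fraction[0, 0] for t in tables]) * 100.0)
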