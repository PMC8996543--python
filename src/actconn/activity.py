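"""Per-ROI activity metrics.

Activity of an ROI is the population variance of its signal across time,

    ac_i = mean((s_i - mean(s_i))^2),

high variance meaning frequent/large signal events.  An alternative
event-integral metric integrates the signal above a baseline mu_i,

    a_i = sum_k (S_{i,k} - mu_i) * dt,

where the baseline is estimated from the "background" samples of the trace
(here: the samples at or below a configurable quantile of the trace; the
default q = 0.5 takes the lower half, which for sparse-event calcium traces
is dominated by the resting baseline).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .signal_io import SignalMatrix

logger = logging.getLogger(__name__)


@dataclass
class ActivityProfile:
    """Per-ROI activity values ac_i.

    ``metric`` is ``"variance"`` or ``"event_integral"``; for the latter the
    per-ROI baseline mu_i is stored as well.
    """

    roi_ids: list[str]
    activity: np.ndarray
    metric: str = "variance"
    baseline: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.activity = np.asarray(self.activity, dtype=float).ravel()
        if len(self.activity) != len(self.roi_ids):
            raise ValueError("activity length must match roi_ids")
        if not np.all(np.isfinite(self.activity)):
            raise ValueError("activity values must be finite")
        if self.metric == "variance" and np.any(self.activity < 0):
            raise ValueError("variance activity must be non-negative")


def compute_activity(m: SignalMatrix) -> ActivityProfile:
    """Variance activity: mean squared deviation from the row mean.

    Uses the population convention (divisor T, not T-1), matching the
    definition ac_i = mean((s_i - mean(s_i))^2).
    """
    act = m.values.var(axis=1)  # ddof=0: divisor T
    return ActivityProfile(roi_ids=list(m.roi_ids), activity=act,
                           metric="variance")


def estimate_baseline(m: SignalMatrix, q: float = 0.5) -> np.ndarray:
    """Baseline mu_i = mean of the samples at or below the q-quantile.

    For a trace that is mostly resting baseline with sparse positive events,
    the sub-quantile samples are background and their mean estimates the
    baseline robustly to the events.  A constant row yields that constant.
    """
    if not 0 < q < 1:
        raise ValueError(f"q must be in (0, 1), got {q}")
    thresh = np.quantile(m.values, q, axis=1, keepdims=True)
    mask = m.values <= thresh
    # every row has at least one sample <= its own quantile
    sums = np.where(mask, m.values, 0.0).sum(axis=1)
    counts = mask.sum(axis=1)
    return sums / counts


def compute_event_integral(m: SignalMatrix,
                           baseline: np.ndarray) -> ActivityProfile:
    """Event-integral activity a_i = sum_k (S_{i,k} - mu_i) * dt."""
    baseline = np.asarray(baseline, dtype=float).ravel()
    if len(baseline) != m.n_rois:
        raise ValueError(f"baseline length {len(baseline)} != R {m.n_rois}")
    act = (m.values - baseline[:, None]).sum(axis=1) * m.dt
    return ActivityProfile(roi_ids=list(m.roi_ids), activity=act,
                           metric="event_integral", baseline=baseline)


def filter_silent_rois(p: ActivityProfile, m: SignalMatrix,
                       min_quantile: float) -> tuple[SignalMatrix,
                                                     ActivityProfile]:
    """Drop ROIs whose activity falls below the cohort quantile.

    ROIs with activity >= the ``min_quantile`` quantile of all activities
    are retained (ties at the threshold are kept).  ``min_quantile = 0`` is
    the identity.  Raises if fewer than 2 ROIs would remain.
    """
    if not 0 <= min_quantile < 1:
        raise ValueError(f"min_quantile must be in [0, 1), got {min_quantile}")
    if list(p.roi_ids) != list(m.roi_ids):
        raise ValueError("ActivityProfile and SignalMatrix roi_ids differ")
    if min_quantile == 0:
        return m, p
    thresh = np.quantile(p.activity, min_quantile)
    keep = p.activity >= thresh
    if keep.sum() < 2:
        raise ValueError(
            f"filtering at quantile {min_quantile} would leave "
            f"{int(keep.sum())} ROI(s); need at least 2")
    removed = [rid for rid, k in zip(p.roi_ids, keep) if not k]
    if removed:
        logger.info("filter_silent_rois: removed %d ROI(s): %s",
                    len(removed), removed[:10])
    kept_ids = [rid for rid, k in zip(p.roi_ids, keep) if k]
    m2 = SignalMatrix(subject_id=m.subject_id, modality=m.modality, dt=m.dt,
                      roi_ids=kept_ids, values=m.values[keep],
                      labels=([l for l, k in zip(m.labels, keep) if k]
                              if m.labels else None),
                      meta={**m.meta, "silent_rois_removed": removed})
    p2 = ActivityProfile(roi_ids=kept_ids, activity=p.activity[keep],
                         metric=p.metric,
                         baseline=(p.baseline[keep]
                                   if p.baseline is not None else None))
    return m2, p2
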