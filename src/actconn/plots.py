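"""Diagnostic figures: threshold scans, relationship curves, joint heatmaps."""

from __future__ import annotations

import numpy as np

from .connectivity import ThresholdScan
from .population import BootstrapBands, CurveBands, JointLevelTable, \
    RelationshipCurve


def _get_ax(ax):
    if ax is None:
        import matplotlib.pyplot as plt
        _, ax = plt.subplots()
    return ax


def plot_threshold_scan(scan: ThresholdScan, ax=None):
    """Power-law fit r^2 across the threshold grid, optimum marked."""
    ax = _get_ax(ax)
    ax.plot(scan.tau_grid, scan.r2, "o-", label="$r^2$ of log-log fit")
    ax.axvline(scan.tau_optimal, color="crimson", ls="--",
               label=f"$\\tau^*$ = {scan.tau_optimal:.2f}")
    ax.set_xlabel(r"threshold $\tau$")
    ax.set_ylabel("power-law fit $r^2$")
    ax.legend()
    return ax


def plot_relationship(curve: RelationshipCurve, ax=None):
    """Degrees vs. activity rank with the LOWESS fit."""
    ax = _get_ax(ax)
    ax.plot(curve.x, curve.y, ".", ms=3, alpha=0.4, label="degree")
    ax.plot(curve.x, curve.y_smooth, "-", lw=2, color="crimson",
            label="LOWESS")
    ax.set_xlabel("ROI rank by activity (ascending)")
    ax.set_ylabel("functional connections (degree)")
    ax.set_title(curve.subject_id)
    ax.legend()
    return ax


def plot_curve_bands(bands: CurveBands, ax=None):
    """Bootstrap mean curve with 95% band on the normalized rank grid."""
    ax = _get_ax(ax)
    ax.fill_between(bands.grid, bands.lo, bands.hi, alpha=0.3,
                    label="95% band")
    ax.plot(bands.grid, bands.mean, lw=2, label="bootstrap mean")
    ax.set_xlabel("normalized activity rank")
    ax.set_ylabel("degree (smoothed)")
    ax.legend()
    return ax


def plot_joint_heatmap(table, ax=None):
    """Heatmap of (activity level, connectivity level) fractions."""
    ax = _get_ax(ax)
    frac = table.fraction if isinstance(table, JointLevelTable) \
        else np.asarray(table.mean if isinstance(table, BootstrapBands)
                        else table)
    im = ax.imshow(frac, cmap="viridis", vmin=0)
    ka, kc = frac.shape
    ax.set_xticks(range(kc), [f"CL-{c + 1}" for c in range(kc)])
    ax.set_yticks(range(ka), [f"AL-{a + 1}" for a in range(ka)])
    for a in range(ka):
        for c in range(kc):
            ax.text(c, a, f"{frac[a, c]:.2f}", ha="center", va="center",
                    color="w" if frac[a, c] < frac.max() / 2 else "k")
    ax.figure.colorbar(im, ax=ax, label="fraction of ROIs")
    return ax
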