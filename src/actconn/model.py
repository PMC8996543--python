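"""Model/Results interface over the full analysis pipeline.

:class:`ActivityConnectivity` is built from one or more subjects' signal
matrices; :meth:`ActivityConnectivity.fit` runs, per subject, the activity
metric, activity-level k-means, Pearson correlation, power-law-optimal
thresholding (or weighted correlation sums), connectivity-level k-means,
the joint level table and the activity-sorted degree curve; across
subjects it bootstraps the joint tables and curves.  The returned
:class:`ActivityConnectivityResults` carries every intermediate, a
``summary()`` table and serialization to CSV/JSON artifacts.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import __version__
from .activity import (ActivityProfile, compute_activity,
                       compute_event_integral, estimate_baseline)
from .connectivity import (ConnectivityProfile, CorrelationMatrix,
                           ThresholdScan, correlation_matrix,
                           optimal_threshold, thresholded_profile,
                           weighted_degree)
from .levels import LevelAssignment, kmeans_levels, level_fractions
from .nulls import (NoiseSpec, SimulatedCohortSpec, add_noise,
                    random_spd_correlation, shuffle_space_time,
                    simulate_from_covariance)
from .population import (BootstrapBands, CurveBands, JointLevelTable,
                         RelationshipCurve, bootstrap_joint_distribution,
                         bootstrap_relationship, exclusivity_statistic,
                         joint_level_fractions, relationship_curve)
from .signal_io import SignalMatrix, load_manifest, znormalize

logger = logging.getLogger(__name__)


@dataclass
class SubjectResult:
    """Every per-subject product of one pipeline run."""

    subject_id: str
    activity: ActivityProfile
    activity_levels: LevelAssignment
    correlation: CorrelationMatrix
    scan: ThresholdScan | None
    connectivity: ConnectivityProfile
    connectivity_levels: LevelAssignment
    joint: JointLevelTable
    curve: RelationshipCurve


class ActivityConnectivity:
    """Joint activity / functional-connectivity model of a cohort.

    Parameters
    ----------
    subjects : sequence of SignalMatrix
        One entry per subject.
    k_levels : int
        Number of k-means levels for both measures (3 by default; 5
        supported).
    tau_grid : array-like, optional
        Candidate correlation thresholds in (0, 1); defaults to
        0.05..0.95 step 0.05.
    connectivity_method : {"thresholded", "weighted_sum"}
        Degree counting at the power-law-optimal threshold, or signed
        correlation sums without thresholding.
    activity_metric : {"variance", "event_integral"}
    baseline_quantile : float
        Background quantile for the event-integral baseline.
    normalize : bool
        Z-normalize each ROI series before analysis (off by default;
        normalizing equalizes all variance activities).
    lowess_frac, robust_iters : LOWESS span and robustifying passes.
    bootstrap_population, bootstrap_curves : bootstrap iteration counts
        for the joint tables (default 25) and the curves (default 7).
    """

    def __init__(self, subjects: Sequence[SignalMatrix], *,
                 k_levels: int = 3, tau_grid=None,
                 connectivity_method: str = "thresholded",
                 activity_metric: str = "variance",
                 baseline_quantile: float = 0.5,
                 normalize: bool = False,
                 weighted_mode: str = "signed",
                 lowess_frac: float = 0.3, robust_iters: int = 0,
                 bootstrap_population: int = 25,
                 bootstrap_curves: int = 7):
        subjects = list(subjects)
        if not subjects:
            raise ValueError("need at least one subject")
        ids = [m.subject_id for m in subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_id in cohort")
        if k_levels < 2:
            raise ValueError("k_levels must be >= 2")
        if connectivity_method not in ("thresholded", "weighted_sum"):
            raise ValueError(f"unknown connectivity_method "
                             f"{connectivity_method!r}")
        if activity_metric not in ("variance", "event_integral"):
            raise ValueError(f"unknown activity_metric {activity_metric!r}")
        self.subjects = subjects
        self.k_levels = int(k_levels)
        self.tau_grid = None if tau_grid is None else \
            np.asarray(tau_grid, dtype=float)
        self.connectivity_method = connectivity_method
        self.activity_metric = activity_metric
        self.baseline_quantile = float(baseline_quantile)
        self.normalize = bool(normalize)
        self.weighted_mode = weighted_mode
        self.lowess_frac = float(lowess_frac)
        self.robust_iters = int(robust_iters)
        self.bootstrap_population = int(bootstrap_population)
        self.bootstrap_curves = int(bootstrap_curves)

    # ------------------------------------------------------------------
    @classmethod
    def from_manifest(cls, path, base_dir=None,
                      **kwargs) -> "ActivityConnectivity":
        """Build the model from a cohort manifest file."""
        manifest = load_manifest(path)
        base = base_dir if base_dir is not None else Path(path).parent
        return cls(manifest.load_subjects(base), **kwargs)

    # ------------------------------------------------------------------
    def _fit_subject(self, m: SignalMatrix) -> SubjectResult:
        if self.normalize:
            m = znormalize(m)
        if self.activity_metric == "variance":
            act = compute_activity(m)
        else:
            act = compute_event_integral(
                m, estimate_baseline(m, self.baseline_quantile))
        al = kmeans_levels(act.activity, k=self.k_levels,
                           roi_ids=act.roi_ids)
        corr = correlation_matrix(m)
        if self.connectivity_method == "thresholded":
            scan = optimal_threshold(corr, self.tau_grid)
            conn = thresholded_profile(corr, scan.tau_optimal)
            logger.info("subject %s: tau*=%.2f r2=%.3f gamma=%.2f",
                        m.subject_id, scan.tau_optimal, scan.r2_optimal,
                        scan.gamma_hat)
        else:
            scan = None
            conn = weighted_degree(corr, mode=self.weighted_mode)
            logger.info("subject %s: weighted correlation sums",
                        m.subject_id)
        cl = kmeans_levels(conn.degrees, k=self.k_levels,
                           roi_ids=conn.roi_ids)
        joint = joint_level_fractions(al, cl, k_activity=self.k_levels,
                                      k_connectivity=self.k_levels,
                                      subject_id=m.subject_id)
        curve = relationship_curve(act, conn, frac=self.lowess_frac,
                                   robust_iters=self.robust_iters,
                                   subject_id=m.subject_id)
        return SubjectResult(subject_id=m.subject_id, activity=act,
                             activity_levels=al, correlation=corr,
                             scan=scan, connectivity=conn,
                             connectivity_levels=cl, joint=joint,
                             curve=curve)

    def fit(self, seed: int = 0) -> "ActivityConnectivityResults":
        """Run the pipeline on every subject and bootstrap the cohort."""
        results = []
        for m in self.subjects:
            try:
                results.append(self._fit_subject(m))
            except Exception as exc:
                raise RuntimeError(
                    f"subject {m.subject_id} failed: {exc}") from exc
        tables = [r.joint for r in results]
        bands = bootstrap_joint_distribution(
            tables, iterations=self.bootstrap_population, seed=seed)
        curves = [r.curve for r in results]
        curve_bands = bootstrap_relationship(
            curves, iterations=self.bootstrap_curves, seed=seed + 1)
        excl = exclusivity_statistic(tables)
        return ActivityConnectivityResults(
            model=self, subject_results=results, joint_bands=bands,
            curve_bands=curve_bands, exclusivity_pct=excl, seed=int(seed))


@dataclass
class ActivityConnectivityResults:
    """Fitted cohort results with summary and serialization."""

    model: ActivityConnectivity
    subject_results: list[SubjectResult]
    joint_bands: BootstrapBands
    curve_bands: CurveBands
    exclusivity_pct: float
    seed: int

    # ------------------------------------------------------------------
    @property
    def mean_joint_table(self) -> pd.DataFrame:
        k = self.model.k_levels
        return pd.DataFrame(self.joint_bands.mean,
                            index=[f"AL-{a + 1}" for a in range(k)],
                            columns=[f"CL-{c + 1}" for c in range(k)])

    def summary(self) -> str:
        """Human-readable cohort report."""
        mdl = self.model
        lines = []
        lines.append("Activity vs. Functional Connectivity".center(72))
        lines.append("=" * 72)
        lines.append(f"Subjects: {len(self.subject_results)}"
                     f"    k levels: {mdl.k_levels}"
                     f"    activity: {mdl.activity_metric}"
                     f"    connectivity: {mdl.connectivity_method}")
        lines.append("-" * 72)
        hdr = f"{'subject':<10}{'R':>6}{'tau*':>7}{'r2*':>7}" \
              + "".join(f"{f'AL{l}%':>7}" for l in range(1, mdl.k_levels + 1)) \
              + "".join(f"{f'CL{l}%':>7}" for l in range(1, mdl.k_levels + 1))
        lines.append(hdr)
        for r in self.subject_results:
            alf = _padded_fractions(r.activity_levels, mdl.k_levels) * 100
            clf = _padded_fractions(r.connectivity_levels,
                                    mdl.k_levels) * 100
            tau = f"{r.scan.tau_optimal:.2f}" if r.scan else "--"
            r2 = f"{r.scan.r2_optimal:.3f}" if r.scan else "--"
            lines.append(f"{r.subject_id:<10}{len(r.activity.activity):>6}"
                         f"{tau:>7}{r2:>7}"
                         + "".join(f"{v:>7.1f}" for v in alf)
                         + "".join(f"{v:>7.1f}" for v in clf))
        lines.append("-" * 72)
        lines.append(f"Joint level fractions, bootstrap mean and 95% bands "
                     f"({self.joint_bands.iterations} iterations):")
        k = mdl.k_levels
        for a in range(k):
            cells = []
            for c in range(k):
                cells.append(f"CL{c + 1}: {self.joint_bands.mean[a, c]:.3f} "
                             f"[{self.joint_bands.lo[a, c]:.3f},"
                             f"{self.joint_bands.hi[a, c]:.3f}]")
            lines.append(f"  AL-{a + 1}  " + "   ".join(cells))
        lines.append(f"Exclusivity (AL-1 & CL-1): "
                     f"{self.exclusivity_pct:.3f}% of ROIs")
        lines.append(f"Mean curve non-increasing over "
                     f"{self.curve_bands.monotone_fraction * 100:.1f}% of "
                     f"the rank grid "
                     f"({self.curve_bands.iterations} curve bootstrap "
                     f"iterations)")
        lines.append("=" * 72)
        return "\n".join(lines)

    # ------------------------------------------------------------------
    def to_report(self) -> dict:
        """JSON-serializable cohort report (deterministic given the fit)."""
        mdl = self.model
        subjects = []
        for r in self.subject_results:
            subjects.append({
                "subject_id": r.subject_id,
                "n_rois": len(r.activity.activity),
                "tau_optimal": (r.scan.tau_optimal if r.scan else None),
                "r2_optimal": (round(r.scan.r2_optimal, 12)
                               if r.scan else None),
                "gamma_hat": (round(r.scan.gamma_hat, 12)
                              if r.scan else None),
                "activity_level_fractions": _round_list(
                    _padded_fractions(r.activity_levels, mdl.k_levels)),
                "connectivity_level_fractions": _round_list(
                    _padded_fractions(r.connectivity_levels, mdl.k_levels)),
                "joint_fractions": [_round_list(row)
                                    for row in r.joint.fraction],
            })
        return {
            "schema_version": 1,
            "package_version": __version__,
            "config": {
                "k_levels": mdl.k_levels,
                "connectivity_method": mdl.connectivity_method,
                "activity_metric": mdl.activity_metric,
                "normalize": mdl.normalize,
                "lowess_frac": mdl.lowess_frac,
                "bootstrap_population": mdl.bootstrap_population,
                "bootstrap_curves": mdl.bootstrap_curves,
                "tau_grid": (_round_list(mdl.tau_grid)
                             if mdl.tau_grid is not None else None),
            },
            "seed": self.seed,
            "subjects": subjects,
            "joint_mean": [_round_list(row) for row in self.joint_bands.mean],
            "joint_lo": [_round_list(row) for row in self.joint_bands.lo],
            "joint_hi": [_round_list(row) for row in self.joint_bands.hi],
            "exclusivity_pct": round(self.exclusivity_pct, 12),
            "curve_monotone_fraction":
                round(self.curve_bands.monotone_fraction, 12),
        }

    def save(self, out_dir) -> Path:
        """Write CSV artifacts and a report.json with content hashes."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        written: list[Path] = []

        def _csv(df: pd.DataFrame, name: str, index: bool = False):
            p = out / name
            df.to_csv(p, index=index, float_format="%.10g",
                      lineterminator="\n")
            written.append(p)

        for r in self.subject_results:
            sid = r.subject_id
            _csv(pd.DataFrame({"roi_id": r.activity.roi_ids,
                               "activity": r.activity.activity,
                               "activity_level": r.activity_levels.level,
                               "degree": r.connectivity.degrees,
                               "connectivity_level":
                                   r.connectivity_levels.level}),
                 f"{sid}_profile.csv")
            if r.scan is not None:
                _csv(r.scan.to_frame(), f"{sid}_threshold_scan.csv")
            _csv(r.joint.to_frame(), f"{sid}_joint_table.csv", index=True)
            _csv(pd.DataFrame({"rank": r.curve.x,
                               "activity": r.curve.activity,
                               "degree": r.curve.y,
                               "degree_smooth": r.curve.y_smooth}),
                 f"{sid}_curve.csv")
        k = self.model.k_levels
        idx = [f"AL-{a + 1}" for a in range(k)]
        cols = [f"CL-{c + 1}" for c in range(k)]
        for name, arr in (("joint_mean", self.joint_bands.mean),
                          ("joint_lo", self.joint_bands.lo),
                          ("joint_hi", self.joint_bands.hi)):
            _csv(pd.DataFrame(arr, index=idx, columns=cols),
                 f"cohort_{name}.csv", index=True)
        _csv(pd.DataFrame({"normalized_rank": self.curve_bands.grid,
                           "mean": self.curve_bands.mean,
                           "lo": self.curve_bands.lo,
                           "hi": self.curve_bands.hi}),
             "cohort_curve_bands.csv")

        report = self.to_report()
        report["artifacts"] = {
            p.name: hashlib.sha256(p.read_bytes()).hexdigest()
            for p in sorted(written)}
        report_path = out / "report.json"
        with open(report_path, "w", encoding="utf-8") as fh:
            json.dump(report, fh, indent=2, sort_keys=True)
            fh.write("\n")
        return report_path


def _padded_fractions(a: LevelAssignment, k: int) -> np.ndarray:
    """Level fractions padded with zeros up to a requested k."""
    f = level_fractions(a)
    if len(f) < k:
        f = np.concatenate([f, np.zeros(k - len(f))])
    return f


def _round_list(arr) -> list:
    return [round(float(v), 12) for v in np.asarray(arr).ravel()]


# ----------------------------------------------------------------------
# Null suite
# ----------------------------------------------------------------------

DEFAULT_NOISE_SCALES = (0.1, 0.5, 1.0, 2.0)


def run_null_suite(subjects: Sequence[SignalMatrix], *, null: str,
                   seed: int = 0, noise_scales=DEFAULT_NOISE_SCALES,
                   per_row: bool = False,
                   **model_kwargs) -> dict[str, ActivityConnectivityResults]:
    """Apply a null model to every subject, then run the identical analysis.

    ``null`` is one of:

    * ``"shuffle"`` — space-time shuffle of each subject;
    * ``"noise"`` — one analysis per scale in ``noise_scales``;
    * ``"cholesky"`` — per subject, a random SPD correlation matrix of the
      same ROI count factorized and used to simulate matched-shape signals.

    Returns a dict tagging each fitted results object by null type and
    parameter.
    """
    subjects = list(subjects)
    out: dict[str, ActivityConnectivityResults] = {}
    if null == "shuffle":
        shuffled = [shuffle_space_time(m, seed + 1 + i, per_row=per_row)
                    for i, m in enumerate(subjects)]
        out["shuffle"] = ActivityConnectivity(
            shuffled, **model_kwargs).fit(seed=seed)
    elif null == "noise":
        for s in noise_scales:
            noisy = [add_noise(m, NoiseSpec(scale=s, seed=seed + 1 + i))
                     for i, m in enumerate(subjects)]
            out[f"noise_{s:g}"] = ActivityConnectivity(
                noisy, **model_kwargs).fit(seed=seed)
    elif null == "cholesky":
        sims = []
        for i, m in enumerate(subjects):
            spec = SimulatedCohortSpec(n_roi=m.n_rois, n_time=m.n_samples,
                                       seed=seed + 1 + i)
            c = random_spd_correlation(spec)
            sim = simulate_from_covariance(c, m.n_samples,
                                           seed=seed + 101 + i, dt=m.dt,
                                           subject_id=f"sim_{m.subject_id}")
            sims.append(sim)
        out["cholesky"] = ActivityConnectivity(
            sims, **model_kwargs).fit(seed=seed)
    else:
        raise ValueError(f"unknown null model {null!r}")
    return out
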