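"""Seeded multi-subject cohort generator with ground-truth ROI archetypes.

The generator emulates the statistical structure the analysis is designed
to detect, in either modality:

* **hub** ROIs share a low-amplitude latent signal (plus a small
  independent residual calibrated so that their pairwise correlation hits
  a target), giving high functional connectivity at low activity;
* **active** ROIs fire independent sparse high-amplitude event trains —
  Poisson events convolved with a calcium-indicator decay kernel (calcium)
  or band-pass filtered (BOLD) — giving high activity with no shared
  structure, hence low connectivity;
* **background** ROIs are observation noise only.

Every ROI additionally receives iid Gaussian observation noise; BOLD
subjects are band-pass filtered as a whole (noise included), mirroring
fMRI preprocessing where filtering follows acquisition.  Because hubs are
*built* to be connected-but-quiet and active ROIs to be loud-but-isolated,
running the full pipeline on these cohorts is a parameter-recovery test of
the method — deliberately not evidence about real brains.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import scipy.signal
import yaml

from .signal_io import (CohortManifest, ManifestEntry, SignalMatrix,
                        save_manifest, write_signal_matrix)

logger = logging.getLogger(__name__)

#: Lognormal sigma of per-event amplitude jitter.
EVENT_AMP_SIGMA = 0.25


@dataclass
class GeneratorConfig:
    """Cohort composition and signal parameters.

    Defaults describe a 200-ROI calcium cohort: 20 hubs (shared latent,
    amplitude 0.3, pairwise correlation 0.8), 20 active ROIs (0.05
    events/s of amplitude 3.0 through a 1.8 s indicator decay), 160
    background ROIs, 1800 frames at dt = 0.5 s, 9 subjects.  BOLD uses
    dt = 2.0 s and a 0.008-0.09 Hz pass band.
    """

    n_hub: int = 20
    n_active: int = 20
    n_background: int = 160
    n_time: int = 1800
    modality: str = "calcium"
    dt: float | None = None
    hub_latent_corr: float = 0.8
    hub_amp: float = 0.3
    active_event_rate: float = 0.05
    active_amp: float = 3.0
    kernel_decay: float = 1.8
    bold_band: tuple[float, float] = (0.008, 0.09)
    obs_noise_sd: float = 0.1
    n_subjects: int = 9
    seed: int = 0

    def __post_init__(self) -> None:
        if self.modality not in ("calcium", "bold"):
            raise ValueError(f"modality must be calcium|bold, "
                             f"got {self.modality!r}")
        if self.dt is None:
            self.dt = 0.5 if self.modality == "calcium" else 2.0
        if self.n_hub + self.n_active + self.n_background < 2:
            raise ValueError("need at least 2 ROIs in total")
        if min(self.n_hub, self.n_active, self.n_background) < 0:
            raise ValueError("archetype counts must be >= 0")
        if not 0 < self.hub_latent_corr < 1:
            raise ValueError("hub_latent_corr must be in (0, 1)")
        for name in ("hub_amp", "active_event_rate", "active_amp",
                     "obs_noise_sd"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        nyq = 1.0 / (2.0 * self.dt)
        lo, hi = self.bold_band
        if not 0 < lo < hi < nyq:
            raise ValueError(f"bold_band must lie within (0, {nyq}) Hz")

    @property
    def n_roi(self) -> int:
        return self.n_hub + self.n_active + self.n_background


@dataclass
class GroundTruth:
    """Designed archetype ('hub' | 'active' | 'background') per ROI."""

    roi_ids: list[str]
    archetype: list[str]

    def __post_init__(self) -> None:
        if len(self.roi_ids) != len(self.archetype):
            raise ValueError("roi_ids and archetype must align")

    def indices(self, kind: str) -> np.ndarray:
        return np.array([i for i, a in enumerate(self.archetype)
                         if a == kind], dtype=int)


# ----------------------------------------------------------------------

def _event_train(rng: np.random.Generator, n_time: int, p_event: float,
                 amp: float) -> np.ndarray:
    """Poisson(p_event) events per frame with lognormal amplitude jitter."""
    counts = rng.poisson(p_event, size=n_time)
    train = np.zeros(n_time)
    total = int(counts.sum())
    if total and amp > 0:
        amps = rng.lognormal(mean=np.log(amp), sigma=EVENT_AMP_SIGMA,
                             size=total)
        np.add.at(train, np.repeat(np.arange(n_time), counts), amps)
    return train


def _calcium_kernel(dt: float, decay: float) -> np.ndarray:
    t = np.arange(0.0, 8.0 * decay, dt)
    return np.exp(-t / decay)


def _bandpass(values: np.ndarray, band: tuple[float, float],
              dt: float) -> np.ndarray:
    fs = 1.0 / dt
    # order-8 Butterworth: transition bands narrow enough that >=95% of
    # each trace's spectral power stays inside the pass band
    sos = scipy.signal.butter(8, band, btype="bandpass", fs=fs,
                              output="sos")
    return scipy.signal.sosfiltfilt(sos, values, axis=-1)


def generate_subject(cfg: GeneratorConfig,
                     subject_index: int) -> tuple[SignalMatrix, GroundTruth]:
    """Generate one subject; deterministic per (cfg.seed, subject_index)."""
    rng = np.random.default_rng(cfg.seed + subject_index)
    r, t = cfg.n_roi, cfg.n_time
    values = np.zeros((r, t))
    archetype = (["hub"] * cfg.n_hub + ["active"] * cfg.n_active
                 + ["background"] * cfg.n_background)
    roi_ids = [f"roi_{i + 1:04d}" for i in range(r)]

    calcium = cfg.modality == "calcium"
    kernel = _calcium_kernel(cfg.dt, cfg.kernel_decay) if calcium else None

    # Shared hub latent: white Gaussian co-fluctuation scaled to hub_amp.
    # Keeping the latent white (rather than indicator-filtered) isolates
    # the designed contrast — hubs correlate through the shared factor
    # only, and actives stay uncorrelated with hubs beyond sampling noise
    # (autocorrelated latents would inflate spurious hub-active sample
    # correlations and blur the archetypes the recovery test relies on).
    if cfg.n_hub:
        latent = rng.standard_normal(t) * cfg.hub_amp
        # independent variance (residual + observation noise) sized so the
        # pairwise hub correlation  var(latent) / (var(latent) + var_ind)
        # hits the target
        var_ind = cfg.hub_amp ** 2 * (1 - cfg.hub_latent_corr) \
            / cfg.hub_latent_corr
        resid_var = max(var_ind - cfg.obs_noise_sd ** 2, 0.0)
        if resid_var == 0.0 and var_ind < cfg.obs_noise_sd ** 2:
            logger.warning("observation noise alone exceeds the "
                           "independent-variance budget; hub correlation "
                           "will undershoot the target")
        values[:cfg.n_hub] = latent + rng.normal(
            0.0, np.sqrt(resid_var), size=(cfg.n_hub, t))

    for i in range(cfg.n_hub, cfg.n_hub + cfg.n_active):
        train = _event_train(rng, t, cfg.active_event_rate * cfg.dt,
                             cfg.active_amp)
        values[i] = np.convolve(train, kernel)[:t] if calcium else train

    values += rng.normal(0.0, cfg.obs_noise_sd, size=(r, t))

    if not calcium:
        if t >= 30:
            values = _bandpass(values, cfg.bold_band, cfg.dt)
        else:
            logger.warning("n_time=%d too short for band-pass filtering; "
                           "skipped", t)

    m = SignalMatrix(subject_id=f"sub_{subject_index:02d}",
                     modality=cfg.modality, dt=cfg.dt, roi_ids=roi_ids,
                     values=values,
                     meta={"generator_seed": int(cfg.seed),
                           "subject_index": int(subject_index)})
    return m, GroundTruth(roi_ids=roi_ids, archetype=archetype)


def generate_subjects(cfg: GeneratorConfig) -> list[tuple[SignalMatrix,
                                                          GroundTruth]]:
    """All subjects of the cohort, in memory."""
    return [generate_subject(cfg, i) for i in range(cfg.n_subjects)]


def generate_cohort(cfg: GeneratorConfig,
                    out_dir) -> tuple[CohortManifest, list[GroundTruth]]:
    """Write the cohort to ``out_dir`` and return its manifest.

    Emits one signal CSV and one ground-truth CSV per subject, a manifest
    YAML, and an echo of the configuration.  Per-subject seeds are
    ``cfg.seed + subject_index``, so identical (cfg, seed) reproduce
    byte-identical files.
    """
    if cfg.n_subjects < 1:
        raise ValueError("n_subjects must be >= 1")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    entries, truths = [], []
    for i in range(cfg.n_subjects):
        m, gt = generate_subject(cfg, i)
        fname = f"{m.subject_id}.csv"
        write_signal_matrix(m, out / fname)
        with open(out / f"{m.subject_id}_ground_truth.csv", "w",
                  encoding="utf-8") as fh:
            fh.write("roi_id,archetype\n")
            for rid, a in zip(gt.roi_ids, gt.archetype):
                fh.write(f"{rid},{a}\n")
        entries.append(ManifestEntry(path=fname, subject_id=m.subject_id,
                                     modality=cfg.modality, dt=cfg.dt))
        truths.append(gt)
    manifest = CohortManifest(entries=entries)
    save_manifest(manifest, out / "manifest.yaml")
    with open(out / "generator_config.yaml", "w", encoding="utf-8") as fh:
        yaml.safe_dump({k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in asdict(cfg).items()}, fh,
                       sort_keys=True)
    return manifest, truths
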