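"""Null-model generators: shuffles, additive Gaussian noise, and
covariance-constrained simulation.

Three controls establish that an observed activity-connectivity structure
is not generic to any set of interconnected signals:

* **shuffle** — one uniformly random permutation of the flattened R x T
  matrix ("across rows and columns"), destroying temporal structure
  everywhere while conserving the multiset of values;
* **noise** — additive iid Normal(0, s) observations, attenuating
  correlations progressively with the noise scale s;
* **simulate** — signals with a prescribed correlation matrix C, built as
  S = L X where L is the Cholesky factor of C and X is iid standard normal.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import scipy.linalg

from .signal_io import SignalMatrix

logger = logging.getLogger(__name__)


@dataclass
class NoiseSpec:
    """Additive Gaussian noise: standard deviation ``scale`` (>= 0)."""

    scale: float
    seed: int = 0

    def __post_init__(self) -> None:
        if not np.isfinite(self.scale) or self.scale < 0:
            raise ValueError(f"noise scale must be finite >= 0, "
                             f"got {self.scale}")


@dataclass
class SimulatedCohortSpec:
    """Shape, seed and factorization jitter of a simulated dataset."""

    n_roi: int
    n_time: int
    seed: int = 0
    jitter: float = 0.05

    def __post_init__(self) -> None:
        if self.n_roi < 2 or self.n_time < 2:
            raise ValueError("n_roi and n_time must be >= 2")
        if not self.jitter > 0:
            raise ValueError("jitter must be > 0")


def shuffle_space_time(m: SignalMatrix, seed: int,
                       per_row: bool = False) -> SignalMatrix:
    """Shuffle a signal matrix across both ROI and time axes.

    Default: a single global permutation of all R*T values, reshaped back
    to R x T.  ``per_row=True`` instead permutes each row independently
    (preserves per-ROI marginals but still destroys temporal alignment).
    Ids, dt and modality are preserved; deterministic given the seed.
    """
    rng = np.random.default_rng(seed)
    if per_row:
        vals = rng.permuted(m.values, axis=1)
    else:
        vals = rng.permutation(m.values.ravel()).reshape(m.values.shape)
    return m.with_values(vals, null_model="shuffle",
                         shuffle_mode="per_row" if per_row else "global",
                         shuffle_seed=int(seed))


def add_noise(m: SignalMatrix, spec: NoiseSpec) -> SignalMatrix:
    """Add iid Normal(0, scale) noise; scale = 0 returns an exact copy."""
    if spec.scale == 0:
        return m.with_values(m.values.copy(), null_model="noise",
                             noise_scale=0.0, noise_seed=int(spec.seed))
    rng = np.random.default_rng(spec.seed)
    vals = m.values + rng.normal(0.0, spec.scale, size=m.values.shape)
    return m.with_values(vals, null_model="noise",
                         noise_scale=float(spec.scale),
                         noise_seed=int(spec.seed))


def random_spd_correlation(spec: SimulatedCohortSpec) -> np.ndarray:
    """Random symmetric positive-definite correlation matrix.

    C0 = A A^T / n + jitter I with A iid standard normal, normalized to
    unit diagonal.  The jitter keeps the smallest eigenvalue away from
    zero; on a (rare) factorization failure it is increased once tenfold.
    """
    rng = np.random.default_rng(spec.seed)
    a = rng.standard_normal((spec.n_roi, spec.n_roi))
    w = a @ a.T / spec.n_roi
    for attempt, jit in enumerate((spec.jitter, 10 * spec.jitter)):
        c0 = w + jit * np.eye(spec.n_roi)
        d = np.sqrt(np.diag(c0))
        c = c0 / np.outer(d, d)
        np.fill_diagonal(c, 1.0)
        try:
            scipy.linalg.cholesky(c, lower=True)
            if attempt:
                logger.warning("random_spd_correlation: jitter increased "
                               "to %g for factorization", jit)
            return c
        except scipy.linalg.LinAlgError:
            continue
    raise ValueError("could not construct a positive-definite correlation "
                     f"matrix (n_roi={spec.n_roi}, jitter={spec.jitter})")


def simulate_from_covariance(c: np.ndarray, n_time: int, seed: int,
                             dt: float = 0.5,
                             subject_id: str = "simulated") -> SignalMatrix:
    """Simulate S = L X with L the lower Cholesky factor of C.

    X is n_roi x n_time iid standard normal, so the rows of S have
    (population) covariance C.  Raises with the failing leading minor if C
    is not symmetric positive-definite.
    """
    c = np.asarray(c, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValueError("C must be square")
    if not np.allclose(c, c.T, atol=1e-10):
        raise ValueError("C must be symmetric")
    try:
        ell = scipy.linalg.cholesky(c, lower=True)
    except scipy.linalg.LinAlgError as exc:
        # scipy's message names the order of the failing leading minor
        raise ValueError(f"C is not positive-definite: {exc}") from exc
    rng = np.random.default_rng(seed)
    x = rng.standard_normal((c.shape[0], n_time))
    s = ell @ x
    ids = [f"roi_{i + 1:04d}" for i in range(c.shape[0])]
    return SignalMatrix(subject_id=subject_id, modality="simulated-calcium",
                        dt=dt, roi_ids=ids, values=s,
                        meta={"null_model": "cholesky", "seed": int(seed)})
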