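import numpy as np
import pytest

from actconn import (ActivityConnectivity, GeneratorConfig, SignalMatrix,
                     generate_subjects)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_matrix(rng):
    """5 ROIs x 60 samples of structured data: two correlated rows, one
    high-variance row, two near-silent rows."""
    t = 60
    shared = rng.normal(0, 1, t)
    values = np.vstack([
        shared + rng.normal(0, 0.2, t),
        shared + rng.normal(0, 0.2, t),
        rng.normal(0, 3.0, t),
        rng.normal(0, 0.05, t),
        rng.normal(0, 0.05, t),
    ])
    return SignalMatrix(subject_id="test", modality="calcium", dt=0.5,
                        roi_ids=[f"r{i}" for i in range(5)], values=values)


@pytest.fixture(scope="session")
def tiny_cohort():
    """3-subject, 30-ROI, 300-frame cohort for fast model-level tests."""
    cfg = GeneratorConfig(n_hub=5, n_active=5, n_background=20, n_time=300,
                          n_subjects=3, seed=11)
    return cfg, generate_subjects(cfg)


@pytest.fixture(scope="session")
def default_cohort():
    """Full generator-default cohort (9 subjects, 200 ROIs, 1800 frames)."""
    cfg = GeneratorConfig(seed=0)
    return cfg, generate_subjects(cfg)


@pytest.fixture(scope="session")
def default_fit(default_cohort):
    """Pipeline results on the generator-default cohort."""
    _, subjects = default_cohort
    model = ActivityConnectivity([m for m, _ in subjects])
    return model.fit(seed=0)
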