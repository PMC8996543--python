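import numpy as np
import pytest

from actconn import (ActivityProfile, ConnectivityProfile, JointLevelTable,
                     bootstrap_joint_distribution, bootstrap_relationship,
                     exclusivity_statistic, joint_level_fractions,
                     level_fractions, relationship_curve)
from actconn.levels import LevelAssignment
from actconn.population import RelationshipCurve


def _assign(levels, k=3):
    levels = np.asarray(levels, dtype=int)
    return LevelAssignment(roi_ids=[f"r{i}" for i in range(len(levels))],
                           level=levels, k=k,
                           centroids=np.arange(k, 0, -1, dtype=float),
                           within_cluster_ss=0.0, requested_k=k)


def _table(frac, sid=""):
    frac = np.asarray(frac, dtype=float)
    return JointLevelTable(k_activity=frac.shape[0],
                           k_connectivity=frac.shape[1], fraction=frac,
                           subject_id=sid)


class TestJointLevelFractions:
    def test_counting_example(self):
        t = joint_level_fractions(_assign([1, 3, 3]), _assign([3, 1, 3]))
        expected = np.zeros((3, 3))
        expected[0, 2] = expected[2, 0] = expected[2, 2] = 1 / 3
        np.testing.assert_allclose(t.fraction, expected)

    def test_identical_assignments_are_diagonal(self, rng):
        lv = rng.integers(1, 4, 30)
        lv[:3] = [1, 2, 3]
        t = joint_level_fractions(_assign(lv), _assign(lv))
        off = t.fraction - np.diag(np.diag(t.fraction))
        np.testing.assert_array_equal(off, 0.0)

    def test_matches_crosstab_oracle_and_marginals(self, rng):
        al = rng.integers(1, 4, 60)
        cl = rng.integers(1, 4, 60)
        al[:3], cl[:3] = [1, 2, 3], [1, 2, 3]
        a, c = _assign(al), _assign(cl)
        t = joint_level_fractions(a, c)
        for i in range(3):
            for j in range(3):
                oracle = np.sum((al == i + 1) & (cl == j + 1)) / 60
                assert t.fraction[i, j] == pytest.approx(oracle)
        # marginals reproduce level_fractions exactly
        np.testing.assert_allclose(t.fraction.sum(axis=1),
                                   level_fractions(a), atol=1e-15)
        np.testing.assert_allclose(t.fraction.sum(axis=0),
                                   level_fractions(c), atol=1e-15)

    def test_mismatched_rois_rejected(self):
        a = _assign([1, 2, 3])
        b = _assign([1, 2, 3])
        b.roi_ids[0] = "other"
        with pytest.raises(ValueError, match="same ROIs"):
            joint_level_fractions(a, b)


class TestBootstrapJoint:
    def test_identical_subjects_zero_dispersion(self):
        t = _table(np.full((3, 3), 1 / 9))
        bands = bootstrap_joint_distribution([t] * 5, iterations=50, seed=0)
        np.testing.assert_allclose(bands.lo, t.fraction, atol=1e-15)
        np.testing.assert_allclose(bands.hi, t.fraction, atol=1e-15)
        np.testing.assert_allclose(bands.mean, t.fraction, atol=1e-15)

    def test_two_disjoint_subjects_binomial_support(self):
        a = np.zeros((2, 2)); a[0, 1] = 1.0
        b = np.zeros((2, 2)); b[1, 0] = 1.0
        bands = bootstrap_joint_distribution([_table(a), _table(b)],
                                             iterations=500, seed=1)
        # each massed cell: resample mean in {0, .5, 1}, expectation .5
        for cell in ((0, 1), (1, 0)):
            assert bands.mean[cell] == pytest.approx(0.5, abs=0.1)
            assert bands.lo[cell] == 0.0
            assert bands.hi[cell] == 1.0

    def test_single_iteration_degenerate(self):
        t1 = _table(np.eye(2) / 2, "a")
        t2 = _table(np.ones((2, 2)) / 4, "b")
        bands = bootstrap_joint_distribution([t1, t2], iterations=1, seed=2)
        np.testing.assert_array_equal(bands.lo, bands.hi)

    def test_heterogeneous_shapes_rejected(self):
        with pytest.raises(ValueError, match="shape"):
            bootstrap_joint_distribution(
                [_table(np.eye(2) / 2), _table(np.eye(3) / 3)])

    def test_mean_converges_to_cohort_mean(self, rng):
        tables = []
        for _ in range(6):
            f = rng.dirichlet(np.ones(9)).reshape(3, 3)
            tables.append(_table(f))
        cohort_mean = np.mean([t.fraction for t in tables], axis=0)
        b = bootstrap_joint_distribution(tables, iterations=1000, seed=3)
        # MC tolerance ~ 3 * SE of a resampled-mean cell
        se = np.std([t.fraction for t in tables], axis=0) \
            / np.sqrt(6 * 1000)
        assert np.all(np.abs(b.mean - cohort_mean) <= 3 * se + 1e-3)


class TestRelationshipCurve:
    def _profiles(self, activity, degs):
        ids = [f"r{i}" for i in range(len(activity))]
        a = ActivityProfile(roi_ids=ids, activity=np.asarray(activity,
                                                             dtype=float))
        c = ConnectivityProfile(roi_ids=ids,
                                degrees=np.asarray(degs, dtype=float),
                                method="thresholded", tau=0.4)
        return a, c

    def test_exact_on_linear_data(self, rng):
        n = 50
        act = rng.permutation(np.linspace(1.0, 9.0, n))
        order = np.argsort(act)
        degs = np.empty(n)
        degs[order] = 2.0 * np.arange(1, n + 1) + 5.0  # linear in rank
        a, c = self._profiles(act, degs)
        curve = relationship_curve(a, c, frac=0.4)
        np.testing.assert_allclose(curve.y_smooth, curve.y, atol=1e-8)

    def test_constant_curve_stays_constant(self):
        a, c = self._profiles(np.arange(20.0), np.full(20, 7.0))
        curve = relationship_curve(a, c)
        np.testing.assert_allclose(curve.y_smooth, 7.0, atol=1e-10)

    def test_matches_pointwise_tricube_wls_oracle(self, rng):
        n = 40
        act = np.arange(1.0, n + 1)
        degs = rng.normal(5, 2, n)
        a, c = self._profiles(act, degs)
        frac = 0.3
        curve = relationship_curve(a, c, frac=frac)
        # independently coded tricube-weighted linear fit at one rank
        x, y = curve.x, curve.y
        for x0_idx in (10, 25):
            x0 = x[x0_idx]
            r = int(frac * n)
            d = np.abs(x - x0)
            h = np.sort(d)[r - 1]
            w = (1 - np.clip(d / h, 0, 1) ** 3) ** 3
            X = np.column_stack([np.ones(n), x])
            beta = np.linalg.solve(X.T @ (w[:, None] * X), X.T @ (w * y))
            oracle = beta[0] + beta[1] * x0
            assert curve.y_smooth[x0_idx] == pytest.approx(oracle, abs=1e-8)

    def test_small_sample_skips_smoothing(self):
        a, c = self._profiles(np.arange(5.0), np.arange(5.0))
        curve = relationship_curve(a, c)
        np.testing.assert_array_equal(curve.y_smooth, curve.y)

    def test_sorted_by_activity(self, rng):
        act = rng.uniform(0.1, 5.0, 30)
        a, c = self._profiles(act, rng.integers(0, 10, 30))
        curve = relationship_curve(a, c)
        assert np.all(np.diff(curve.activity) >= 0)


class TestBootstrapRelationship:
    def _curve(self, y, sid="s"):
        y = np.asarray(y, dtype=float)
        x = np.arange(1.0, len(y) + 1)
        return RelationshipCurve(subject_id=sid, x=x, y=y, y_smooth=y,
                                 activity=x)

    def test_identical_curves_zero_width_band(self):
        c = self._curve(np.linspace(10, 2, 30))
        bands = bootstrap_relationship([c] * 4, iterations=20, seed=0)
        np.testing.assert_allclose(bands.lo, bands.hi, atol=1e-12)
        np.testing.assert_allclose(bands.mean, bands.lo, atol=1e-12)

    def test_strictly_decreasing_mean_is_fully_monotone(self):
        curves = [self._curve(np.linspace(8 + i, i, 25), sid=str(i))
                  for i in range(3)]
        bands = bootstrap_relationship(curves, iterations=30, seed=1)
        assert bands.monotone_fraction == 1.0

    def test_interpolation_handles_unequal_lengths(self):
        curves = [self._curve(np.linspace(5, 1, 20)),
                  self._curve(np.linspace(5, 1, 35))]
        bands = bootstrap_relationship(curves, iterations=10, seed=2)
        assert bands.grid.shape == bands.mean.shape == (101,)
        assert bands.mean[0] == pytest.approx(5.0, abs=1e-9)
        assert bands.mean[-1] == pytest.approx(1.0, abs=1e-9)


class TestExclusivity:
    def test_extreme_tables(self):
        empty = np.zeros((3, 3)); empty[2, 2] = 1.0
        full = np.zeros((3, 3)); full[0, 0] = 1.0
        assert exclusivity_statistic([_table(empty)]) == 0.0
        assert exclusivity_statistic([_table(full)]) == 100.0

    def test_mixed_cohort_matches_averaging_oracle(self, rng):
        tables = []
        for _ in range(5):
            f = rng.dirichlet(np.ones(9)).reshape(3, 3)
            tables.append(_table(f))
        oracle = 100.0 * np.mean([t.fraction[0, 0] for t in tables])
        assert exclusivity_statistic(tables) == pytest.approx(oracle)
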