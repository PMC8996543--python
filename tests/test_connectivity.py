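import numpy as np
import networkx as nx
import pytest

from actconn import (SignalMatrix, correlation_matrix, threshold_binarize,
                     degrees, degree_distribution, powerlaw_r2,
                     optimal_threshold, thresholded_profile, weighted_degree,
                     DEFAULT_TAU_GRID, GeneratorConfig, generate_subject,
                     SimulatedCohortSpec, random_spd_correlation)
from actconn.connectivity import CorrelationMatrix, edge_list


def _matrix(values, dt=0.5):
    values = np.asarray(values, dtype=float)
    return SignalMatrix(subject_id="s", modality="calcium", dt=dt,
                        roi_ids=[f"r{i}" for i in range(values.shape[0])],
                        values=values)


def _corr_from(rho):
    rho = np.asarray(rho, dtype=float)
    return CorrelationMatrix(roi_ids=[f"r{i}" for i in range(len(rho))],
                             rho=rho,
                             zero_variance_flags=np.zeros(len(rho), bool))


class TestCorrelationMatrix:
    def test_self_and_anti_correlation(self, rng):
        x = rng.normal(0, 1, 30)
        m = _matrix(np.vstack([x, -x + 7.0, rng.normal(0, 1, 30)]))
        c = correlation_matrix(m)
        assert c.rho[0, 0] == 1.0
        assert c.rho[0, 1] == pytest.approx(-1.0, abs=1e-12)
        assert np.all(np.abs(c.rho) <= 1.0)
        np.testing.assert_allclose(c.rho, c.rho.T, atol=1e-10)

    def test_matches_textbook_formula_oracle(self, rng):
        vals = rng.normal(0, 2, (3, 20))
        c = correlation_matrix(_matrix(vals))
        for i in range(3):
            for j in range(3):
                xi, xj = vals[i] - vals[i].mean(), vals[j] - vals[j].mean()
                oracle = (xi * xj).mean() / (xi.std() * xj.std())
                assert c.rho[i, j] == pytest.approx(oracle, abs=1e-12)

    def test_zero_variance_rows_flagged_and_zeroed(self, rng):
        vals = np.vstack([np.full(20, 3.0), rng.normal(0, 1, (2, 20))])
        c = correlation_matrix(_matrix(vals))
        assert c.zero_variance_flags[0] and not c.zero_variance_flags[1:].any()
        assert np.all(c.rho[0, 1:] == 0.0) and np.all(c.rho[1:, 0] == 0.0)
        assert c.rho[0, 0] == 1.0

    def test_invariant_to_positive_affine_transforms(self, rng):
        vals = rng.normal(0, 1, (4, 50))
        c1 = correlation_matrix(_matrix(vals))
        scales = rng.uniform(0.5, 4.0, 4)[:, None]
        shifts = rng.normal(0, 10, 4)[:, None]
        c2 = correlation_matrix(_matrix(vals * scales + shifts))
        np.testing.assert_allclose(c2.rho, c1.rho, atol=1e-9)


class TestThresholdAndDegrees:
    def test_binarize_known_edges(self):
        c = _corr_from([[1, .6, .2], [.6, 1, .7], [.2, .7, 1]])
        adj = threshold_binarize(c, 0.5)
        expected = np.array([[0, 1, 0], [1, 0, 1], [0, 1, 0]], bool)
        np.testing.assert_array_equal(adj, expected)
        np.testing.assert_array_equal(degrees(adj), [1, 2, 1])

    def test_threshold_above_all_and_strict_boundary(self):
        c = _corr_from([[1, .9, .3], [.9, 1, .5], [.3, .5, 1]])
        assert not threshold_binarize(c, 0.999).any()
        # rho exactly equal to tau -> no edge (strict inequality)
        adj = threshold_binarize(c, 0.9)
        assert not adj[0, 1] and not adj[1, 0]

    def test_degrees_validates_input(self):
        bad = np.array([[0, 1], [0, 0]], bool)
        with pytest.raises(ValueError, match="symmetric"):
            degrees(bad)
        with pytest.raises(ValueError, match="diagonal"):
            degrees(np.eye(3, dtype=bool))

    def test_degrees_match_networkx_oracle(self, rng):
        # Erdos-Renyi sample cross-checked against the graph library
        g = nx.erdos_renyi_graph(25, 0.2, seed=5)
        adj = nx.to_numpy_array(g, dtype=bool)
        ours = degrees(adj)
        theirs = np.array([d for _, d in sorted(g.degree())])
        np.testing.assert_array_equal(ours, theirs)

    def test_adjacency_consistent_with_direct_pair_count(self, rng):
        vals = rng.normal(0, 1, (10, 40))
        c = correlation_matrix(_matrix(vals))
        tau = 0.2
        prof = thresholded_profile(c, tau)
        direct = [(np.delete(c.rho[i], i) > tau).sum() for i in range(10)]
        np.testing.assert_array_equal(prof.degrees, direct)


class TestDegreeDistribution:
    def test_counting(self):
        assert degree_distribution([1, 2, 1]) == {1: 2 / 3, 2: 1 / 3}
        assert degree_distribution([4, 4, 4]) == {4: 1.0}

    def test_matches_counting_oracle_and_normalization(self, rng):
        deg = rng.integers(0, 8, 60)
        dist = degree_distribution(deg)
        for k, p in dist.items():
            assert p == pytest.approx(np.sum(deg == k) / 60)
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)


class TestPowerlawFit:
    def test_exact_power_law_is_perfect(self):
        raw = {k: k ** -2.0 for k in range(1, 9)}
        z = sum(raw.values())
        r2, gamma = powerlaw_r2({k: v / z for k, v in raw.items()})
        assert r2 == pytest.approx(1.0, abs=1e-9)
        assert gamma == pytest.approx(2.0, abs=1e-9)

    def test_uniform_distribution_flat_fit(self):
        r2, gamma = powerlaw_r2({k: 1 / 8 for k in range(1, 9)})
        assert r2 == pytest.approx(1.0, abs=1e-12)
        assert gamma == pytest.approx(0.0, abs=1e-9)

    def test_matches_closed_form_ols_oracle(self):
        dist = {1: 0.4, 2: 0.25, 3: 0.15, 5: 0.12, 9: 0.08}
        r2, gamma = powerlaw_r2(dist)
        x = np.log10(np.array(sorted(dist)))
        y = np.log10(np.array([dist[k] for k in sorted(dist)]))
        sxx = ((x - x.mean()) ** 2).sum()
        sxy = ((x - x.mean()) * (y - y.mean())).sum()
        syy = ((y - y.mean()) ** 2).sum()
        slope = sxy / sxx
        assert gamma == pytest.approx(-slope, abs=1e-12)
        assert r2 == pytest.approx(sxy ** 2 / (sxx * syy), abs=1e-12)

    def test_undefined_below_three_bins_and_k0_excluded(self):
        assert powerlaw_r2({0: 0.5, 1: 0.3, 2: 0.2}) is None
        assert powerlaw_r2({1: 0.6, 2: 0.4}) is None
        # k = 0 never enters: identical fit with and without the 0 bin
        with_zero = {0: 0.4, 1: 0.3, 2: 0.2, 3: 0.1}
        rescaled = {1: 0.3, 2: 0.2, 3: 0.1}
        r2a, ga = powerlaw_r2(with_zero)
        r2b, gb = powerlaw_r2(rescaled)
        assert ga == pytest.approx(gb, abs=1e-12)


class TestOptimalThreshold:
    def test_tie_break_smallest_tau(self):
        # identical adjacency (hence identical r2) at every grid point:
        # edges at rho=0.5 produce degrees {3,2,2,1,1,1,0,0}
        rho = np.full((8, 8), 0.05)
        edges = [(0, 1), (0, 2), (0, 3), (1, 2), (4, 5)]
        for i, j in edges:
            rho[i, j] = rho[j, i] = 0.5
        np.fill_diagonal(rho, 1.0)
        scan = optimal_threshold(_corr_from(rho),
                                 tau_grid=[0.1, 0.2, 0.3])
        assert np.nanstd(scan.r2) == pytest.approx(0.0, abs=1e-12)
        assert scan.tau_optimal == 0.1

    def test_argmax_selects_peak(self):
        m, _ = generate_subject(GeneratorConfig(seed=7), 0)
        scan = optimal_threshold(correlation_matrix(m))
        best = np.nanargmax(scan.r2)
        assert scan.tau_optimal == scan.tau_grid[best]
        assert scan.r2_optimal == np.nanmax(scan.r2)
        assert 0 < scan.tau_optimal < 1

    def test_scan_deterministic_and_frozen_regression(self):
        # generator subject (default config, seed 7): value frozen from an
        # implementation run as a regression guard
        m, _ = generate_subject(GeneratorConfig(seed=7), 0)
        c = correlation_matrix(m)
        s1, s2 = optimal_threshold(c), optimal_threshold(c)
        assert s1.tau_optimal == s2.tau_optimal == 0.05
        np.testing.assert_array_equal(s1.r2, s2.r2)

    def test_no_defined_fit_raises(self):
        rho = np.eye(4)
        with pytest.raises(ValueError, match="tau grid|power-law"):
            optimal_threshold(_corr_from(rho))

    def test_grid_validation(self):
        c = _corr_from(np.eye(3))
        for bad in ([0.5, 0.4], [0.0, 0.5], [0.5, 1.0]):
            with pytest.raises(ValueError):
                optimal_threshold(c, tau_grid=bad)

    def test_degree_monotonicity_in_tau(self):
        # nested edge sets: degrees can only shrink as tau grows
        for seed in range(10):
            c_mat = random_spd_correlation(
                SimulatedCohortSpec(n_roi=15, n_time=10, seed=seed))
            c = _corr_from(c_mat)
            prev = None
            for tau in DEFAULT_TAU_GRID:
                deg = degrees(threshold_binarize(c, tau))
                if prev is not None:
                    assert np.all(deg <= prev)
                prev = deg


class TestWeightedDegree:
    def test_two_roi_single_term(self):
        prof = weighted_degree(_corr_from([[1.0, 0.8], [0.8, 1.0]]))
        np.testing.assert_allclose(prof.degrees, [0.8, 0.8])
        assert prof.method == "weighted_sum" and prof.tau is None

    def test_identity_matrix_gives_zeros(self):
        prof = weighted_degree(_corr_from(np.eye(4)))
        np.testing.assert_array_equal(prof.degrees, 0.0)

    def test_matches_row_sum_oracle_and_modes(self, rng):
        a = rng.uniform(-1, 1, (6, 6))
        rho = (a + a.T) / 2
        np.fill_diagonal(rho, 1.0)
        signed = weighted_degree(_corr_from(rho)).degrees
        oracle = rho.sum(axis=1) - np.diag(rho)
        np.testing.assert_allclose(signed, oracle, atol=1e-12)
        absolute = weighted_degree(_corr_from(rho), mode="absolute").degrees
        positive = weighted_degree(_corr_from(rho), mode="positive").degrees
        assert np.all(absolute >= signed - 1e-12)
        assert np.all(positive >= 0)


def test_edge_list_upper_triangle(rng):
    vals = rng.normal(0, 1, (5, 30))
    c = correlation_matrix(_matrix(vals))
    adj = threshold_binarize(c, 0.1)
    df = edge_list(c, adj)
    assert len(df) == adj.sum() // 2
    assert (df["rho"] > 0.1).all()
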