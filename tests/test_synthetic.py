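import numpy as np
import pytest

from comorbmap.data_model import Covariate, CovariateSchema, RegionGraph
from comorbmap.design import mrf_precision
from comorbmap.synthetic import (SimulationConfig, SmoothSpec,
                                 simulate_dataset, simulate_region_effects)


class TestRegionEffects:
    def test_vanishing_structured_variance(self, lattice):
        f_str, _ = simulate_region_effects(lattice, 1e-12, 0.01, 1)
        assert np.max(np.abs(f_str)) < 1e-4

    def test_two_region_pairwise_difference_variance(self):
        """The 2-region intrinsic-MRF density is exp(-(f1-f2)^2 / (2 tau2)),
        so the pairwise difference has variance tau2 — consistent with the
        covariance oracle tau2 * pinv(K), under which (1,-1) pinv(K) (1,-1)'
        equals 1."""
        g = RegionGraph.from_edges(["A", "B"], [("A", "B")])
        tau2 = 0.7
        rng = np.random.default_rng(42)
        diffs = np.array([np.subtract(*simulate_region_effects(g, tau2, 1e-12, rng)[0])
                          for _ in range(10_000)])
        se = np.sqrt(2) * tau2 / np.sqrt(10_000)  # SE of a variance estimate
        assert abs(diffs.var() - tau2) < 4 * se

    def test_covariance_matches_pseudoinverse(self, lattice):
        """Sample covariance of centred draws ~ tau2 * pinv(K)."""
        tau2 = 0.5
        rng = np.random.default_rng(7)
        draws = np.array([simulate_region_effects(lattice, tau2, 1e-12, rng)[0]
                          for _ in range(10_000)])
        emp = np.cov(draws.T)
        expected = tau2 * np.linalg.pinv(mrf_precision(lattice).matrix)
        assert np.max(np.abs(emp - expected)) < 0.12 * np.max(np.abs(expected))

    def test_disconnected_graph_rejected(self):
        g = RegionGraph.from_edges(["A", "B", "C", "D"],
                                   [("A", "B"), ("C", "D")])
        with pytest.raises(ValueError, match="disconnected"):
            simulate_region_effects(g, 0.1, 0.1, 0)


class TestSimulateDataset:
    def test_deterministic_under_seed(self):
        a, _ = simulate_dataset(SimulationConfig(seed=3, n_children=500))
        b, _ = simulate_dataset(SimulationConfig(seed=3, n_children=500))
        c, _ = simulate_dataset(SimulationConfig(seed=4, n_children=500))
        assert a.records.equals(b.records)
        assert not a.records.equals(c.records)

    def test_zero_effects_give_uniform_categories(self):
        cfg = SimulationConfig(seed=1, n_children=10_000, spatial=False,
                               smooth=None, true_fixed_effects={},
                               category_targets=(0.25, 0.25, 0.25, 0.25))
        ds, truth = simulate_dataset(cfg)
        assert np.allclose(truth.intercepts, 0.0, atol=1e-8)
        freq = ds.category_counts() / ds.n
        se = np.sqrt(0.25 * 0.75 / ds.n)
        assert np.all(np.abs(freq - 0.25) < 3 * se)

    def test_default_marginals_near_published(self):
        ds, _ = simulate_dataset(SimulationConfig(seed=9))
        assert ds.n == 8742
        freq = ds.category_counts() / ds.n
        targets = np.array(SimulationConfig(seed=9).category_targets)
        se = np.sqrt(targets * (1 - targets) / ds.n)
        assert np.all(np.abs(freq - targets) < 3.5 * se)

    def test_binary_covariate_log_odds_ratio_recovered(self):
        """Empirical 2x2 log-OR (categories 0 vs 1) matches the true 1.0."""
        schema = CovariateSchema((Covariate("x", ("a", "b"), "a"),))
        cfg = SimulationConfig(
            seed=11, n_children=100_000, spatial=False, smooth=None,
            schema=schema, covariate_frequencies={"x": {"a": 0.5, "b": 0.5}},
            true_fixed_effects={"x=b": (1.0, 0.0, 0.0)},
            category_targets=(0.5, 0.3, 0.12, 0.08))
        ds, _ = simulate_dataset(cfg)
        df = ds.records
        t = np.array([[((df["x"] == lev) & (df["outcome"] == l)).sum()
                       for l in (0, 1)] for lev in ("a", "b")], dtype=float)
        log_or = np.log(t[1, 1] * t[0, 0] / (t[1, 0] * t[0, 1]))
        se = np.sqrt((1.0 / t).sum())
        assert abs(log_or - 1.0) < 3 * se

    def test_true_age_curve_peaks_in_window(self):
        curve = SmoothSpec().curve(np.arange(60))
        for l in range(3):
            assert 10 <= np.argmax(curve[:, l]) <= 15

    def test_probabilities_partition(self):
        # generator invariant: per-child category probabilities sum to one
        from comorbmap.design import category_probabilities
        eta = np.random.default_rng(0).normal(size=(50, 3)) * 3
        assert np.allclose(category_probabilities(eta).sum(axis=1), 1.0,
                           atol=1e-14)

    def test_planted_region_effect_recorded(self, lattice):
        cfg = SimulationConfig(seed=2, n_children=300,
                               planted_region="Harari", planted_effect=2.0)
        _, truth = simulate_dataset(cfg, lattice)
        j = lattice.index("Harari")
        others = np.delete(truth.f_str, j, axis=1)
        assert np.all(truth.f_str[:, j] > others.max(axis=1))
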