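import numpy as np
import pytest
from scipy import stats

from comorbmap._pg import pg_mean, polya_gamma
from comorbmap.inference import (MCMCOptions, PriorSpec, diagnostics, fit,
                                 update_variance)
from comorbmap.model_selection import ModelSpec, model_spec
from comorbmap.synthetic import SimulationConfig, simulate_dataset

from conftest import make_dataset

INTERCEPT_ONLY = ModelSpec(False, False, False, False, "intercept")


def _categorical(rng, probs, n):
    return rng.choice(len(probs), size=n, p=probs)


class TestPolyaGamma:
    def test_mean_identity(self):
        rng = np.random.default_rng(0)
        for z in (0.0, 0.5, 2.0, 8.0, -3.0):
            d = polya_gamma(np.full(50_000, z), rng)
            se = d.std() / np.sqrt(len(d))
            assert abs(d.mean() - pg_mean(np.array([z]))[0]) < 4 * se

    def test_laplace_transform(self):
        # E exp(-omega t) = cosh(z/2) / cosh(sqrt(z^2/4 + t/2))
        rng = np.random.default_rng(1)
        d = polya_gamma(np.full(200_000, 1.5), rng)
        for t in (0.5, 4.0):
            exact = np.cosh(0.75) / np.cosh(np.sqrt(1.5 ** 2 / 4 + t / 2))
            emp = np.exp(-d * t)
            assert abs(emp.mean() - exact) < 4 * emp.std() / np.sqrt(len(d))


class TestUpdateVariance:
    def test_zero_coefficients_identity_penalty(self):
        rng = np.random.default_rng(2)
        a, b, m = 2.0, 1.5, 8
        draws = np.array([update_variance(np.zeros(m), np.eye(m), a, b, rng)
                          for _ in range(100_000)])
        expected = b / (a + m / 2 - 1)  # IG mean with shape a+m/2, scale b
        assert abs(draws.mean() - expected) < 4 * draws.std() / np.sqrt(len(draws))

    def test_default_hyperparameters_accepted(self):
        p = PriorSpec()  # a = 1, b = 0.005 defaults
        assert p.ab("smooth") == (1.0, 0.005)
        assert p.ab("str") == (1.0, 0.005)

    def test_distribution_matches_inverse_gamma(self):
        rng = np.random.default_rng(3)
        a, b = 1.0, 0.005
        beta = np.array([0.3, -0.2, 0.1])
        K = np.diag([1.0, 2.0, 0.5])
        quad = beta @ K @ beta
        draws = np.array([update_variance(beta, K, a, b, rng)
                          for _ in range(100_000)])
        ref = stats.invgamma(a + 1.5, scale=b + quad / 2)
        assert stats.kstest(draws, ref.cdf).pvalue > 0.01

    def test_non_psd_penalty_rejected(self):
        with pytest.raises(ValueError, match="positive semi-definite"):
            update_variance(np.ones(2), np.array([[1.0, 0], [0, -1.0]]),
                            1.0, 1.0, np.random.default_rng(0))


@pytest.mark.parametrize("method", ["pg", "iwls"])
class TestConjugateOracles:
    def test_intercept_only_matches_empirical_logit(self, method):
        rng = np.random.default_rng(7)
        n = 3000
        y = _categorical(rng, [0.55, 0.22, 0.15, 0.08], n)
        ds = make_dataset(y)
        s = fit(ds, None, INTERCEPT_ONLY,
                options=MCMCOptions(iterations=1200, burnin=400, thin=2,
                                    seed=1), method=method)
        counts = np.bincount(y, minlength=4)
        for l in (1, 2, 3):
            d = s.fixed_draws(l)[:, 0]
            target = np.log(counts[l] / counts[0])
            mcse = d.std() / np.sqrt(len(d) / 8)  # generous autocorr factor
            assert abs(d.mean() - target) < max(3 * mcse, 0.03)

    def test_binary_covariate_matches_table_log_or(self, method):
        rng = np.random.default_rng(8)
        n = 20_000
        sex = np.where(rng.random(n) < 0.5, "male", "female")
        base = np.array([0.55, 0.22, 0.15, 0.08])
        shifted = base * np.exp([0.0, 0.5, -0.3, 0.2])
        shifted /= shifted.sum()
        y = np.where(sex == "male", _categorical(rng, base, n),
                     _categorical(rng, shifted, n))
        ds = make_dataset(y, sex=sex)
        s = fit(ds, None, model_spec("M1"),
                options=MCMCOptions(iterations=900, burnin=300, thin=2,
                                    seed=2), method=method)
        j = s.fixed_labels.index("sex=female")
        t = np.array([[((sex == g) & (y == l)).sum() for l in range(4)]
                      for g in ("male", "female")], dtype=float)
        for l in (1, 2, 3):
            d = s.fixed_draws(l)[:, j]
            target = np.log(t[1, l] * t[0, 0] / (t[1, 0] * t[0, l]))
            se = np.sqrt(1 / t[1, l] + 1 / t[0, 0] + 1 / t[1, 0] + 1 / t[0, l])
            assert abs(d.mean() - target) < 3 * se


class TestSamplerMechanics:
    def test_bit_exact_seed_reproducibility(self):
        ds, _ = simulate_dataset(SimulationConfig(seed=4, n_children=400))
        opts = MCMCOptions(iterations=60, burnin=20, thin=2, seed=9)
        a = fit(ds, None, model_spec("M2"), options=opts)
        b = fit(ds, None, model_spec("M2"), options=opts)
        assert all(np.array_equal(a.coef[k], b.coef[k]) for k in a.coef)
        assert np.array_equal(a.deviance, b.deviance)

    def test_stored_draw_count(self):
        ds, _ = simulate_dataset(SimulationConfig(seed=4, n_children=200))
        s = fit(ds, None, INTERCEPT_ONLY,
                options=MCMCOptions(iterations=100, burnin=40, thin=3, seed=0))
        assert s.n_draws == 20

    def test_centred_effects_sum_to_zero(self, lattice):
        ds, _ = simulate_dataset(SimulationConfig(seed=6, n_children=600))
        s = fit(ds, lattice, model_spec("M6"),
                options=MCMCOptions(iterations=50, burnin=20, thin=1, seed=0))
        for kind in ("str", "unstr"):
            sums = s.coef[kind].sum(axis=2)
            assert np.max(np.abs(sums)) < 1e-10
        assert np.all(s.tau2["str"] > 0)

    def test_spatial_model_requires_graph(self):
        ds, _ = simulate_dataset(SimulationConfig(seed=4, n_children=200))
        with pytest.raises(ValueError, match="graph required"):
            fit(ds, None, model_spec("M5"))

    def test_structured_requires_connected_graph(self):
        from comorbmap.data_model import RegionGraph
        g = RegionGraph.from_edges(["A", "B", "C"], [("A", "B")])
        ds = make_dataset([0, 1, 2, 3], regions=["A", "B", "C", "A"],
                          clusters=["cA", "cB", "cC", "cA"])
        with pytest.raises(ValueError, match="connected"):
            fit(ds, g, model_spec("M5"))

    def test_save_load_roundtrip(self, tmp_path):
        ds, _ = simulate_dataset(SimulationConfig(seed=4, n_children=200))
        s = fit(ds, None, model_spec("M2"),
                options=MCMCOptions(iterations=40, burnin=10, thin=1, seed=0))
        s.save(tmp_path / "store")
        from comorbmap.inference import PosteriorSamples
        back = PosteriorSamples.load(tmp_path / "store")
        assert back.model == s.model
        for k in s.coef:
            assert np.allclose(back.coef[k], s.coef[k])
        assert np.allclose(back.deviance, s.deviance)

    def test_posterior_sd_shrinks_like_root_n(self):
        """log-log slope of posterior SD vs n is about -1/2."""
        sds = []
        sizes = [500, 2000, 8000]
        for i, n in enumerate(sizes):
            cfg = SimulationConfig(seed=20 + i, n_children=n, spatial=False,
                                   smooth=None)
            ds, _ = simulate_dataset(cfg)
            s = fit(ds, None, model_spec("M1"),
                    options=MCMCOptions(iterations=500, burnin=150, thin=2,
                                        seed=30 + i))
            j = s.fixed_labels.index("sex=female")
            sds.append(s.fixed_draws(1)[:, j].std())
        slope = np.polyfit(np.log(sizes), np.log(sds), 1)[0]
        assert abs(slope + 0.5) < 0.15


class TestDiagnostics:
    def test_iid_chain_rhat_near_one(self):
        x = np.random.default_rng(0).normal(size=2000)
        d = diagnostics({"a": x})
        assert abs(d.loc[0, "rhat"] - 1.0) < 0.02
        assert not d.loc[0, "flag"]

    def test_constant_chain_flagged_not_crashed(self):
        d = diagnostics({"a": np.ones(500)})
        assert bool(d.loc[0, "flag"])
        assert "degenerate" in d.loc[0, "note"]

    def test_ar1_effective_size(self):
        rho = 0.9
        rng = np.random.default_rng(1)
        n = 40_000
        x = np.empty(n)
        x[0] = rng.normal()
        for i in range(1, n):
            x[i] = rho * x[i - 1] + np.sqrt(1 - rho ** 2) * rng.normal()
        d = diagnostics({"a": x})
        expected = n * (1 - rho) / (1 + rho)
        assert abs(d.loc[0, "ess"] - expected) / expected < 0.2

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            diagnostics({"a": np.random.default_rng(0).normal(size=50)})
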