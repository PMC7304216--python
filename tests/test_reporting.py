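import numpy as np
import pytest

from comorbmap.inference import MCMCOptions, PosteriorSamples, PriorSpec, fit
from comorbmap.model_selection import ModelSpec, model_spec
from comorbmap.reporting import (PUBLISHED_CROSSTABS, crosstab_chisq,
                                 crosstab_from_counts, descriptive_table,
                                 or_summary, smooth_bands,
                                 spatial_significance)
from comorbmap.synthetic import SimulationConfig, simulate_dataset


def pearson_chi2(counts):
    """Independent hand computation of the Pearson statistic."""
    counts = np.asarray(counts, dtype=float)
    row, col, tot = counts.sum(1), counts.sum(0), counts.sum()
    E = np.outer(row, col) / tot
    return ((counts - E) ** 2 / E).sum()


class TestCrosstabs:
    @pytest.mark.parametrize("covariate,printed_p", [
        ("anemia", 0.040), ("working", 0.002), ("household_size", 0.009),
        ("birth_order", 0.002), ("water", 0.038),
    ])
    def test_published_tables_reproduce_printed_p(self, covariate, printed_p):
        tab = PUBLISHED_CROSSTABS[covariate]
        ct = crosstab_from_counts(covariate, list(tab), list(tab.values()))
        assert round(ct.p_value, 3) == printed_p
        # cross-check the statistic against an independent Pearson computation
        from scipy.stats import chi2
        x2 = pearson_chi2(list(tab.values()))
        assert ct.chi2 == pytest.approx(x2, rel=1e-12)
        assert ct.df == (len(tab) - 1) * 3
        assert ct.p_value == pytest.approx(chi2.sf(x2, ct.df), rel=1e-12)

    def test_identical_rows_give_independence(self):
        ct = crosstab_from_counts("x", ["a", "b"],
                                  [[10, 20, 30, 40], [10, 20, 30, 40]])
        assert ct.chi2 == pytest.approx(0.0, abs=1e-12)
        assert ct.p_value == pytest.approx(1.0)

    def test_zero_margin_rejected(self):
        with pytest.raises(ValueError, match="zero margin"):
            crosstab_from_counts("x", ["a", "b"],
                                 [[0, 0, 0, 0], [1, 2, 3, 4]])

    def test_dataset_crosstab_row_percentages(self, default_sim):
        ds, _ = default_sim
        ct = crosstab_chisq(ds, "sex")
        assert np.allclose(ct.row_percent.sum(axis=1), 100.0, atol=0.1)
        assert ct.counts.sum() == ds.n

    def test_descriptive_table_shape(self, default_sim):
        ds, _ = default_sim
        t = descriptive_table(ds)
        n_levels = sum(len(c.levels) for c in ds.schema)
        assert len(t) == n_levels
        # p-values printed to 3 decimals
        p = t["p_value"].dropna()
        assert np.allclose(p, p.round(3))


def _manual_samples(fixed_draws_by_cat, region_draws=None, region_ids=None):
    """Assemble a PosteriorSamples object from explicit draw arrays."""
    S = fixed_draws_by_cat.shape[0]
    coef = {"fixed": fixed_draws_by_cat}
    if region_draws is not None:
        coef["str"] = region_draws
    return PosteriorSamples(
        model=ModelSpec(True, False, region_draws is not None, False, "manual"),
        coef=coef, tau2={}, deviance=np.zeros(S),
        fixed_labels=tuple(f"b{j}" for j in range(fixed_draws_by_cat.shape[2])),
        region_ids=region_ids, spline=None,
        options=MCMCOptions(iterations=S + 1, burnin=0, thin=1, seed=0),
        priors=PriorSpec(), method="pg")


class TestORSummary:
    def test_constant_zero_draws(self):
        s = _manual_samples(np.zeros((200, 3, 2)))
        t = or_summary(s)
        assert np.allclose(t["or_mean"], 1.0)
        assert np.allclose(t["ci_2.5"], 1.0)
        assert not t["significant"].any()

    def test_lognormal_oracle(self):
        rng = np.random.default_rng(0)
        mu, sigma = np.log(2.0), 0.01
        draws = rng.normal(mu, sigma, size=(5000, 3, 1))
        t = or_summary(_manual_samples(draws))
        expected_mean = np.exp(mu + sigma ** 2 / 2)
        assert np.allclose(t["or_mean"], expected_mean, atol=4 * sigma)
        assert np.allclose(t["ci_2.5"],
                           np.exp(mu - 1.96 * sigma), atol=3e-3)
        assert t["significant"].all()

    def test_requires_100_draws(self):
        with pytest.raises(ValueError, match="100"):
            or_summary(_manual_samples(np.zeros((50, 3, 1))))


class TestSpatialSignificance:
    def test_all_zero_draws_class_zero(self):
        s = _manual_samples(np.zeros((200, 3, 1)),
                            region_draws=np.zeros((200, 3, 3)),
                            region_ids=("A", "B", "C"))
        t = spatial_significance(s)
        assert (t["class"] == 0).all()

    def test_constant_positive_region(self):
        d = np.zeros((200, 3, 3))
        d[:, :, 1] = 0.5
        s = _manual_samples(np.zeros((200, 3, 1)), region_draws=d,
                            region_ids=("A", "B", "C"))
        t = spatial_significance(s)
        assert (t.loc[t["region_id"] == "B", "class"] == 1).all()
        assert (t.loc[t["region_id"] != "B", "class"] == 0).all()

    def test_missing_term_rejected(self):
        s = _manual_samples(np.zeros((200, 3, 1)))
        with pytest.raises(ValueError, match="spatial term"):
            spatial_significance(s)


class TestSmoothBands:
    @pytest.fixture(scope="class")
    def smooth_fit(self):
        ds, _ = simulate_dataset(SimulationConfig(seed=13, n_children=800,
                                                  spatial=False))
        s = fit(ds, None, model_spec("M2"),
                options=MCMCOptions(iterations=300, burnin=100, thin=2, seed=3))
        return s

    def test_bands_nested(self, smooth_fit):
        c = smooth_bands(smooth_fit)
        assert np.all(c.lo95 <= c.lo80)
        assert np.all(c.hi80 <= c.hi95)
        assert np.all(c.lo80 <= c.mean + 1e-12)
        assert np.all(c.mean <= c.hi80 + 1e-12)

    def test_constant_draws_zero_width(self, smooth_fit):
        import copy
        frozen = copy.deepcopy(smooth_fit)
        frozen.coef["smooth"][:] = frozen.coef["smooth"][0]
        c = smooth_bands(frozen)
        assert np.allclose(c.lo95, c.hi95)
        assert np.allclose(c.mean, c.lo80)

    def test_grid_outside_range_rejected(self, smooth_fit):
        with pytest.raises(ValueError, match="outside"):
            smooth_bands(smooth_fit, grid=np.array([-5.0, 70.0]))
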