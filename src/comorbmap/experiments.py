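"""Validation experiments: parameter recovery, model recovery, prior recovery.

These are the package's evidence that the machinery works: they generate
data from the synthetic module under known ground truth, run the samplers
and hotspot analysis, and measure recovery. The analysis drivers, the test
suite and the acceptance script all call these functions.

Seeds derived here stay below 2**31.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from .data_model import Covariate, CovariateSchema, Dataset, RegionGraph
from .hotspot import hotspots
from .inference import MCMCOptions, PriorSpec, fit
from .model_selection import compare, model_spec
from .synthetic import (GroundTruth, SimulationConfig, SmoothSpec,
                        lattice11_graph, simulate_dataset)

_SEED_MOD = 2_000_000_011  # keep derived seeds well under 2**31


def _derive(seed: int, salt: int) -> int:
    return (seed * 1_000_003 + salt) % _SEED_MOD


def truth_coefficients(truth: GroundTruth,
                       fixed_labels: tuple[str, ...]) -> np.ndarray:
    """(3, p) true fixed-effect values aligned to design column labels."""
    out = np.zeros((3, len(fixed_labels)))
    for j, lab in enumerate(fixed_labels):
        if lab == "intercept":
            out[:, j] = truth.intercepts
        else:
            out[:, j] = np.asarray(truth.fixed_effects.get(lab, (0.0, 0.0, 0.0)))
    return out


# ---------------------------------------------------------------------------
# fixed-effect credible-interval coverage
# ---------------------------------------------------------------------------

def coverage_experiment(n_reps: int = 100, n_children: int = 8742,
                        iterations: int = 320, burnin: int = 100,
                        thin: int = 2, seed: int = 0) -> dict:
    """Replicate fits of the fixed-effects model on matched synthetic truth.

    Each replicate draws a fresh dataset from a non-spatial, non-smooth
    (fixed-effects-only) ground truth, fits the fixed-effects model, and
    checks whether each coefficient's central 95% credible interval covers
    its true value. Returns the pooled coverage percentage.
    """
    graph = lattice11_graph()
    covered = 0
    total = 0
    per_rep = []
    for rep in range(n_reps):
        cfg = SimulationConfig(seed=_derive(seed, rep), spatial=False,
                               smooth=None, n_children=n_children)
        ds, truth = simulate_dataset(cfg, graph)
        s = fit(ds, None, model_spec("M1"),
                options=MCMCOptions(iterations=iterations, burnin=burnin,
                                    thin=thin, seed=_derive(seed, 50_000 + rep)))
        tv = truth_coefficients(truth, s.fixed_labels)
        hit = 0
        for l in range(1, 4):
            draws = s.fixed_draws(l)
            lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
            hit += int(np.sum((lo <= tv[l - 1]) & (tv[l - 1] <= hi)))
        npar = 3 * len(s.fixed_labels)
        covered += hit
        total += npar
        per_rep.append(hit / npar)
    return {"coverage_pct": 100.0 * covered / total, "n_intervals": total,
            "n_reps": n_reps, "per_rep": per_rep}


# ---------------------------------------------------------------------------
# age-curve peak recovery
# ---------------------------------------------------------------------------

def age_peak_experiment(n_reps: int = 10, n_children: int = 8742,
                        iterations: int = 600, burnin: int = 200,
                        thin: int = 4, seed: int = 0,
                        window: tuple[float, float] = (10.0, 15.0)) -> dict:
    """Does the posterior-mean age curve peak in the true 10-15 month window?

    Data come from a smooth-plus-fixed truth whose curve peaks at 12 months;
    each replicate fits the fixed+smooth model and records the argmax of the
    recovered posterior-mean curve of category 1 on a fine age grid.
    """
    peaks = []
    for rep in range(n_reps):
        cfg = SimulationConfig(seed=_derive(seed, 300 + rep), spatial=False,
                               n_children=n_children)
        ds, truth = simulate_dataset(cfg)
        s = fit(ds, None, model_spec("M2"),
                options=MCMCOptions(iterations=iterations, burnin=burnin,
                                    thin=thin, seed=_derive(seed, 60_000 + rep)))
        grid = np.linspace(s.spline["x_min"], s.spline["x_max"], 200)
        curve = s.smooth_draws(1, grid).mean(axis=0)
        peaks.append(float(grid[np.argmax(curve)]))
    peaks = np.array(peaks)
    n_in = int(np.sum((peaks >= window[0]) & (peaks <= window[1])))
    return {"peaks": peaks.tolist(), "n_in_window": n_in, "n_reps": n_reps}


# ---------------------------------------------------------------------------
# DIC model recovery
# ---------------------------------------------------------------------------

def dic_recovery_experiment(n_seeds: int = 10, n_children: int = 3000,
                            iterations: int = 450, burnin: int = 150,
                            thin: int = 3, seed: int = 0) -> dict:
    """Generate from a fixed+smooth+structured (M5-type) truth and ask how
    often the DIC-minimal model among M1-M6 contains both the smooth and the
    structured term (i.e. is M5 or M6)."""
    graph = lattice11_graph()
    best = []
    tables = []
    for rep in range(n_seeds):
        cfg = SimulationConfig(seed=_derive(seed, 700 + rep), spatial=True,
                               unstructured=False, n_children=n_children)
        ds, _ = simulate_dataset(cfg, graph)
        tab = compare(ds, graph,
                      options=MCMCOptions(iterations=iterations, burnin=burnin,
                                          thin=thin,
                                          seed=_derive(seed, 70_000 + rep)))
        name = tab.loc[tab["DIC"].idxmin(), "model"]
        best.append(name)
        tables.append(tab)
    n_ok = sum(model_spec(b).smooth and model_spec(b).structured for b in best)
    return {"best_models": best, "n_smooth_and_structured": n_ok,
            "n_seeds": n_seeds, "tables": tables}


# ---------------------------------------------------------------------------
# planted-hotspot detection
# ---------------------------------------------------------------------------

def planted_hotspot_experiment(n_seeds: int = 10, region: str = "Oromia",
                               effect: float = 1.0, n_children: int = 8742,
                               seed: int = 0) -> dict:
    """Give one region a large positive structured effect and check the
    Gi* analysis puts the majority of its 'high' clusters there."""
    graph = lattice11_graph()
    hits = 0
    for rep in range(n_seeds):
        cfg = SimulationConfig(seed=_derive(seed, 900 + rep),
                               n_children=n_children,
                               planted_region=region, planted_effect=effect)
        ds, _ = simulate_dataset(cfg, graph)
        res = hotspots(ds)
        high = res.table.loc[res.table["cls"] == "high", "region_id"]
        if len(high) and high.value_counts().idxmax() == region:
            hits += 1
    return {"hits": hits, "n_seeds": n_seeds, "region": region}


# ---------------------------------------------------------------------------
# "getting it right": successive-conditional prior recovery
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GirConfig:
    """Small proper-prior model for the prior-recovery check.

    All priors must be proper to be simulated from, so the smooth and MRF
    structure matrices are ridge-augmented to full rank, centring is off and
    the fixed effects get a Gaussian prior. The identical sampler code path
    is exercised.
    """

    n: int = 40
    m_basis_interior: int = 2   # m = interior + degree + 1 = 6 basis functions
    degree: int = 3
    fixed_sd: float = 1.5
    ridge: float = 0.3
    a: float = 3.0
    b: float = 2.0
    sweeps_per_cycle: int = 4
    #: the chain's memory is intrinsic to the cycle (weakly informative data
    #: keep consecutive posteriors near each other, whatever the sweep
    #: count), so calibration of the KS test comes from heavy thinning of
    #: many cycles rather than from more sweeps
    n_cycles: int = 2500


def _gir_dataset(outcomes, ages, regions, clusters, schema, coords):
    rec = pd.DataFrame({"outcome": outcomes, "age_months": ages,
                        "region_id": regions, "cluster_id": clusters,
                        "sex": np.where(np.arange(len(ages)) % 2 == 0,
                                        "male", "female")})
    return Dataset(records=rec, cluster_coords=coords, schema=schema)


def getting_it_right(cfg: GirConfig = GirConfig(), seed: int = 1) -> dict:
    """Run the successive-conditional simulator and compare parameter
    marginals with their priors.

    Cycle: draw all parameters from the (proper) priors once at the start;
    then repeatedly (a) simulate outcomes given the current parameters and
    (b) advance the parameters by a few MCMC sweeps on the new data. If the
    transition kernel targets the right posterior, the stationary marginal
    of every parameter is its prior. Returns Kolmogorov-Smirnov p-values of
    a fixed coefficient against N(0, sd^2) and of each variance against its
    inverse gamma.
    """
    rng = np.random.default_rng(seed)
    graph = RegionGraph.from_edges(["A", "B", "C"], [("A", "B"), ("B", "C")])
    schema = CovariateSchema((Covariate("sex", ("male", "female"), "male"),))
    n = cfg.n
    ages = np.floor(np.linspace(0, 59.999, n))
    regions = np.array(["A", "B", "C"])[np.arange(n) % 3]
    clusters = np.char.add("c_", regions.astype(str))
    coords = pd.DataFrame({"lon": [34.0, 35.0, 36.0], "lat": [8.0, 8.0, 8.0]},
                          index=pd.Index(["c_A", "c_B", "c_C"], name="cluster_id"))

    from .design import bspline_basis, mrf_precision
    basis = bspline_basis(ages, n_interior_knots=cfg.m_basis_interior,
                          degree=cfg.degree)
    Ks = basis.penalty + cfg.ridge * np.eye(basis.m)
    Km = mrf_precision(graph).matrix + cfg.ridge * np.eye(3)
    sex = (np.arange(n) % 2 != 0).astype(float)  # matches _gir_dataset
    Xf = np.column_stack([np.ones(n), sex])
    priors = PriorSpec(a_smooth=cfg.a, b_smooth=cfg.b, a_str=cfg.a, b_str=cfg.b,
                       fixed_prior_sd=cfg.fixed_sd)
    spec = model_spec("M5")  # fixed + smooth + structured

    def prior_draw():
        tau2 = {"smooth": cfg.b / rng.standard_gamma(cfg.a, 3),
                "str": cfg.b / rng.standard_gamma(cfg.a, 3)}
        coef = {"fixed": rng.normal(0, cfg.fixed_sd, (3, 2)),
                "smooth": np.stack([
                    np.linalg.cholesky(np.linalg.inv(Ks / t)) @
                    rng.standard_normal(basis.m) for t in tau2["smooth"]]),
                "str": np.stack([
                    np.linalg.cholesky(np.linalg.inv(Km / t)) @
                    rng.standard_normal(3) for t in tau2["str"]])}
        return coef, tau2

    def simulate_outcomes(coef):
        eta = (Xf @ coef["fixed"].T + basis.matrix @ coef["smooth"].T)
        zidx = np.arange(n) % 3
        eta = eta + coef["str"].T[zidx]
        from .design import category_probabilities
        pi = category_probabilities(eta)
        u = rng.random(n)
        return (u[:, None] > np.cumsum(pi, axis=1)).sum(axis=1)

    coef, tau2 = prior_draw()
    kept = {"beta_sex_cat1": [], "tau2_smooth_cat1": [], "tau2_str_cat2": []}
    for cycle in range(cfg.n_cycles):
        y = simulate_outcomes(coef)
        ds = _gir_dataset(y, ages.astype(int), regions, clusters, schema, coords)
        s = fit(ds, graph, spec, priors=priors,
                options=MCMCOptions(iterations=cfg.sweeps_per_cycle,
                                    burnin=cfg.sweeps_per_cycle - 1, thin=1,
                                    seed=0),
                n_interior_knots=cfg.m_basis_interior, degree=cfg.degree,
                center=False, smooth_ridge=cfg.ridge, mrf_ridge=cfg.ridge,
                init_state={"coef": coef, "tau2": tau2}, rng=rng)
        coef = {nm: s.final_state["coef"][nm] for nm in ("fixed", "smooth", "str")}
        tau2 = {nm: s.final_state["tau2"][nm] for nm in ("smooth", "str")}
        kept["beta_sex_cat1"].append(coef["fixed"][0, 1])
        kept["tau2_smooth_cat1"].append(tau2["smooth"][0])
        kept["tau2_str_cat2"].append(tau2["str"][1])

    thin = 25  # keep near-independent cycles so the KS test is calibrated
    beta = np.array(kept["beta_sex_cat1"])[::thin]
    t_s = np.array(kept["tau2_smooth_cat1"])[::thin]
    t_m = np.array(kept["tau2_str_cat2"])[::thin]
    p_beta = stats.kstest(beta, stats.norm(0, cfg.fixed_sd).cdf).pvalue
    p_ts = stats.kstest(t_s, stats.invgamma(cfg.a, scale=cfg.b).cdf).pvalue
    p_tm = stats.kstest(t_m, stats.invgamma(cfg.a, scale=cfg.b).cdf).pvalue
    return {"p_beta": float(p_beta), "p_tau2_smooth": float(p_ts),
            "p_tau2_str": float(p_tm), "n_kept": len(beta)}
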