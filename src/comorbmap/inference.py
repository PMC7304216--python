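"""MCMC for the Bayesian geoadditive baseline-category logit.

The four-category outcome is modelled with category-0 as baseline
(eta_0 = 0) and per-category predictors built from any subset of: fixed
effects (flat prior by default), a P-spline age smooth (RW2 prior, variance
tau2_smooth), an intrinsic-MRF structured region effect (variance tau2_str)
and an iid unstructured region effect (variance tau2_unstr). Variances get
inverse-gamma IG(a, b) hyperpriors, default a = 1, b = 0.005.

Sampling decomposes the multinomial into per-category conditional binary
logits: conditioning on the other categories' predictors, the indicator
1{y = l} is Bernoulli with logit eta_l - log(1 + sum_{k != l} exp eta_k).
Polya-Gamma augmentation then gives exact multivariate-Gaussian full
conditionals for every coefficient block and IG full conditionals for every
variance — a pure Gibbs sweep. A metropolized IWLS proposal (the classic
structured-additive-regression update) is available via ``method="iwls"``.

Identifiability: the smooth's fitted values and both region-effect vectors
are recentred to mean zero every sweep, the removed constants absorbed into
the category intercept (the RW2 and intrinsic-MRF priors are flat in those
directions). ``center=False`` disables this, for use with the proper-prior
variants (``smooth_ridge`` / ``mrf_ridge`` > 0, Gaussian fixed-effect prior).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.interpolate import BSpline
from scipy.linalg import cholesky, solve_triangular
from scipy.special import expit

from ._pg import polya_gamma
from .data_model import Dataset, RegionGraph
from .design import (SplineBasis, bspline_basis, build_fixed_design,
                     mrf_precision, region_indicator)
from .model_selection import ModelSpec, deviance

N_CATEGORIES = 3  # non-reference categories 1..3

__all__ = [
    "PriorSpec", "MCMCOptions", "PosteriorSamples", "fit",
    "update_variance", "diagnostics",
]


@dataclass(frozen=True)
class PriorSpec:
    """Inverse-gamma (a, b) per variance; fixed-effect prior flat or Gaussian.

    ``fixed_prior_sd=None`` means the improper uniform prior on fixed
    effects; a float requests independent N(0, sd^2) priors instead.
    """

    a_smooth: float = 1.0
    b_smooth: float = 0.005
    a_str: float = 1.0
    b_str: float = 0.005
    a_unstr: float = 1.0
    b_unstr: float = 0.005
    fixed_prior_sd: float | None = None

    def __post_init__(self):
        for nm in ("a_smooth", "b_smooth", "a_str", "b_str", "a_unstr", "b_unstr"):
            if getattr(self, nm) <= 0:
                raise ValueError(f"{nm} must be > 0")
        if self.fixed_prior_sd is not None and self.fixed_prior_sd <= 0:
            raise ValueError("fixed_prior_sd must be > 0 (or None for flat)")

    def ab(self, name: str) -> tuple[float, float]:
        return getattr(self, f"a_{name}"), getattr(self, f"b_{name}")


@dataclass(frozen=True)
class MCMCOptions:
    iterations: int = 12_000
    burnin: int = 2_000
    thin: int = 10
    seed: int = 0

    def __post_init__(self):
        if not (self.iterations > self.burnin >= 0):
            raise ValueError("need iterations > burnin >= 0")
        if self.thin < 1:
            raise ValueError("thinning must be >= 1")

    @property
    def n_stored(self) -> int:
        return (self.iterations - self.burnin + self.thin - 1) // self.thin


@dataclass
class PosteriorSamples:
    """Stored MCMC draws plus everything needed to re-evaluate the predictor.

    ``coef[name]`` has shape (draws, 3, p_name) for name in
    {"fixed", "smooth", "str", "unstr"}; ``tau2[name]`` has shape (draws, 3);
    ``deviance`` one value per stored draw.
    """

    model: ModelSpec
    coef: dict[str, np.ndarray]
    tau2: dict[str, np.ndarray]
    deviance: np.ndarray
    fixed_labels: tuple[str, ...]
    region_ids: tuple[str, ...] | None
    spline: dict | None            # knots, degree, x_min, x_max
    options: MCMCOptions
    priors: PriorSpec
    method: str = "pg"
    centered: bool = True

    @property
    def n_draws(self) -> int:
        return len(self.deviance)

    def fixed_draws(self, category: int) -> np.ndarray:
        """(draws, p) fixed-effect draws for outcome category 1, 2 or 3."""
        return self.coef["fixed"][:, category - 1, :]

    def spatial_draws(self, category: int, kind: str = "str") -> np.ndarray:
        return self.coef[kind][:, category - 1, :]

    def smooth_basis(self) -> SplineBasis | None:
        if self.spline is None:
            return None
        sp = self.spline
        knots = np.asarray(sp["knots"])
        # penalty not needed for evaluation; rebuild for completeness
        m = len(knots) - sp["degree"] - 1
        D2 = np.diff(np.eye(m), n=2, axis=0)
        return SplineBasis(knots=knots, degree=sp["degree"],
                           matrix=np.zeros((0, m)), penalty=D2.T @ D2,
                           x_min=sp["x_min"], x_max=sp["x_max"])

    def smooth_draws(self, category: int, grid: np.ndarray) -> np.ndarray:
        """(draws, len(grid)) evaluations of f_l on an age grid."""
        basis = self.smooth_basis()
        if basis is None:
            raise ValueError("model has no smooth term")
        Bg = basis.evaluate(np.asarray(grid, dtype=float))
        return self.coef["smooth"][:, category - 1, :] @ Bg.T

    # -- predictor reconstruction -------------------------------------------
    def predict_eta(self, dataset: Dataset, graph: RegionGraph | None = None,
                    at_mean: bool = True) -> np.ndarray:
        """(n, 3) predictor at the posterior means of all coefficient blocks."""
        if not at_mean:
            raise NotImplementedError("only the plug-in posterior mean is supported")
        n = dataset.n
        eta = np.zeros((n, N_CATEGORIES))
        Xf = self._fixed_matrix(dataset)
        for l in range(N_CATEGORIES):
            eta[:, l] += Xf @ self.coef["fixed"][:, l, :].mean(axis=0)
        if "smooth" in self.coef:
            basis = self.smooth_basis()
            B = basis.evaluate(dataset.records["age_months"].to_numpy(dtype=float))
            for l in range(N_CATEGORIES):
                eta[:, l] += B @ self.coef["smooth"][:, l, :].mean(axis=0)
        if ("str" in self.coef) or ("unstr" in self.coef):
            if graph is None:
                raise ValueError("graph required to rebuild spatial terms")
            Z = region_indicator(dataset, graph)
            if tuple(graph.region_ids) != tuple(self.region_ids):
                raise ValueError("graph region ordering differs from the fit")
            for kind in ("str", "unstr"):
                if kind in self.coef:
                    for l in range(N_CATEGORIES):
                        eta[:, l] += Z @ self.coef[kind][:, l, :].mean(axis=0)
        return eta

    def _fixed_matrix(self, dataset: Dataset) -> np.ndarray:
        if self.model.fixed:
            fd = build_fixed_design(dataset)
            if fd.labels != self.fixed_labels:
                raise ValueError("dataset design columns differ from the fit")
            return fd.matrix
        return np.ones((dataset.n, 1))

    # -- persistence: one CSV per block + JSON sidecar ----------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        meta = {
            "model": asdict(self.model),
            "options": asdict(self.options),
            "priors": asdict(self.priors),
            "method": self.method,
            "centered": self.centered,
            "fixed_labels": list(self.fixed_labels),
            "region_ids": list(self.region_ids) if self.region_ids else None,
            "spline": (None if self.spline is None else
                       {**self.spline, "knots": list(map(float, self.spline["knots"]))}),
            "blocks": sorted(self.coef),
            "tau2": sorted(self.tau2),
        }
        (d / "metadata.json").write_text(json.dumps(meta, indent=1), "utf-8")
        for name, arr in self.coef.items():
            S, _, p = arr.shape
            cols = {f"cat{l+1}_{j}": arr[:, l, j]
                    for l in range(N_CATEGORIES) for j in range(p)}
            pd.DataFrame(cols).to_csv(d / f"coef_{name}.csv", index=False)
        tau_cols = {f"{name}_cat{l+1}": arr[:, l]
                    for name, arr in self.tau2.items() for l in range(N_CATEGORIES)}
        pd.DataFrame({**tau_cols, "deviance": self.deviance}).to_csv(
            d / "scalars.csv", index=False)

    @classmethod
    def load(cls, directory) -> "PosteriorSamples":
        d = Path(directory)
        meta = json.loads((d / "metadata.json").read_text("utf-8"))
        model = ModelSpec(**meta["model"])
        coef = {}
        for name in meta["blocks"]:
            df = pd.read_csv(d / f"coef_{name}.csv")
            p = sum(c.startswith("cat1_") for c in df.columns)
            arr = np.empty((len(df), N_CATEGORIES, p))
            for l in range(N_CATEGORIES):
                for j in range(p):
                    arr[:, l, j] = df[f"cat{l+1}_{j}"]
            coef[name] = arr
        sc = pd.read_csv(d / "scalars.csv")
        tau2 = {}
        for name in meta["tau2"]:
            arr = np.column_stack([sc[f"{name}_cat{l+1}"] for l in range(N_CATEGORIES)])
            tau2[name] = arr
        return cls(model=model, coef=coef, tau2=tau2,
                   deviance=sc["deviance"].to_numpy(),
                   fixed_labels=tuple(meta["fixed_labels"]),
                   region_ids=(tuple(meta["region_ids"])
                               if meta["region_ids"] else None),
                   spline=meta["spline"],
                   options=MCMCOptions(**meta["options"]),
                   priors=PriorSpec(**meta["priors"]),
                   method=meta["method"], centered=meta["centered"])


# ---------------------------------------------------------------------------
# variance full conditional
# ---------------------------------------------------------------------------

def update_variance(coefficients: np.ndarray, penalty: np.ndarray,
                    a: float, b: float, rng: np.random.Generator,
                    rank: int | None = None) -> float:
    """Draw tau^2 from its inverse-gamma full conditional.

    With a Gaussian smoothness prior beta | tau^2 ~ N(0, (K/tau^2)^-) of
    rank k and hyperprior tau^2 ~ IG(a, b), the full conditional is
    IG(a + k/2, b + beta' K beta / 2).
    """
    beta = np.asarray(coefficients, dtype=float)
    K = np.asarray(penalty, dtype=float)
    if K.shape[0] != K.shape[1] or not np.allclose(K, K.T, atol=1e-12):
        raise ValueError("penalty must be symmetric")
    ev = np.linalg.eigvalsh(K)
    if ev.min() < -1e-8 * max(1.0, ev.max()):
        raise ValueError("penalty must be positive semi-definite")
    if rank is None:
        rank = int(np.sum(ev > 1e-10 * max(1.0, ev.max())))
    quad = float(beta @ K @ beta)
    return _ig_draw(a + rank / 2.0, b + max(quad, 0.0) / 2.0, rng)


def _ig_draw(shape: float, scale: float, rng: np.random.Generator) -> float:
    return scale / rng.standard_gamma(shape)


# ---------------------------------------------------------------------------
# the sampler
# ---------------------------------------------------------------------------

@dataclass
class _Term:
    name: str
    X: np.ndarray
    K: np.ndarray | None       # structure matrix scaled by 1/tau2 (None = fixed prior)
    rank: int = 0
    sample_tau2: bool = False
    center: str | None = None  # None | "fitted" (smooth) | "coef" (spatial)
    fixed_prec: np.ndarray | None = None  # constant prior precision (fixed block)
    group_idx: np.ndarray | None = None   # set when X is a 0/1 group indicator


#: tiny ridge on the flat-prior fixed block: numerically a N(0, 1e8) prior,
#: operationally the improper uniform.
_FLAT_RIDGE = 1e-8


def fit(dataset: Dataset, graph: RegionGraph | None, model: ModelSpec,
        priors: PriorSpec | None = None, options: MCMCOptions | None = None,
        method: str = "pg", n_interior_knots: int = 20, degree: int = 3,
        center: bool = True, smooth_ridge: float = 0.0,
        mrf_ridge: float = 0.0, init_tau2: float = 0.1,
        init_state: dict | None = None,
        rng: np.random.Generator | None = None) -> PosteriorSamples:
    """Run the Gibbs (or metropolized-IWLS) sampler for one model form.

    ``smooth_ridge`` / ``mrf_ridge`` add eps*I to the RW2 / MRF structure
    matrices, making those priors proper (used by the prior-recovery
    validation and available to users who prefer proper priors); the default
    0 is the improper intrinsic form with per-sweep recentring.
    """
    priors = priors or PriorSpec()
    options = options or MCMCOptions()
    if method not in ("pg", "iwls"):
        raise ValueError("method must be 'pg' or 'iwls'")
    if model.needs_graph:
        if graph is None:
            raise ValueError(f"model {model.name} includes spatial terms: graph required")
        dataset.validate_against(graph)
    if model.structured and graph is not None and not graph.is_connected():
        raise ValueError("structured spatial term requires a connected region graph")

    if rng is None:
        rng = np.random.default_rng(options.seed)
    n = dataset.n
    y = dataset.records["outcome"].to_numpy()
    yind = np.stack([(y == l + 1).astype(float) for l in range(N_CATEGORIES)])

    terms: list[_Term] = []
    if model.fixed:
        fd = build_fixed_design(dataset)
        Xf, fixed_labels = fd.matrix, fd.labels
    else:
        Xf, fixed_labels = np.ones((n, 1)), ("intercept",)
    pf = Xf.shape[1]
    if priors.fixed_prior_sd is None:
        fixed_prec = _FLAT_RIDGE * np.eye(pf)
    else:
        fixed_prec = np.eye(pf) / priors.fixed_prior_sd ** 2
    terms.append(_Term("fixed", Xf, None, fixed_prec=fixed_prec))

    spline_meta = None
    if model.smooth:
        basis = bspline_basis(dataset.records["age_months"].to_numpy(dtype=float),
                              n_interior_knots=n_interior_knots, degree=degree)
        Ks = basis.penalty + smooth_ridge * np.eye(basis.m)
        rank = basis.m if smooth_ridge > 0 else basis.penalty_rank
        terms.append(_Term("smooth", basis.matrix, Ks, rank=rank,
                           sample_tau2=True, center="fitted" if center else None))
        spline_meta = {"knots": basis.knots, "degree": basis.degree,
                       "x_min": basis.x_min, "x_max": basis.x_max}

    region_ids = None
    if model.structured or model.unstructured:
        Z = region_indicator(dataset, graph)
        region_ids = graph.region_ids
        R = graph.n_regions
        ridx = np.argmax(Z, axis=1)
        if model.structured:
            Km = mrf_precision(graph).matrix + mrf_ridge * np.eye(R)
            rank = R if mrf_ridge > 0 else R - 1
            terms.append(_Term("str", Z, Km, rank=rank, sample_tau2=True,
                               center="coef" if center else None,
                               group_idx=ridx))
        if model.unstructured:
            terms.append(_Term("unstr", Z, np.eye(R), rank=R, sample_tau2=True,
                               center="coef" if center else None,
                               group_idx=ridx))

    # state (optionally warm-started, e.g. by prior-recovery validation)
    coef = {t.name: np.zeros((N_CATEGORIES, t.X.shape[1])) for t in terms}
    tau2 = {t.name: np.full(N_CATEGORIES, init_tau2)
            for t in terms if t.sample_tau2}
    if init_state is not None:
        for nm, v in init_state.get("coef", {}).items():
            coef[nm] = np.array(v, dtype=float)
        for nm, v in init_state.get("tau2", {}).items():
            tau2[nm] = np.array(v, dtype=float)
    fitted = {t.name: coef[t.name] @ t.X.T for t in terms}
    eta = np.zeros((N_CATEGORIES, n))
    for t in terms:
        eta += fitted[t.name]

    S = options.n_stored
    store_coef = {t.name: np.empty((S, N_CATEGORIES, t.X.shape[1])) for t in terms}
    store_tau2 = {nm: np.empty((S, N_CATEGORIES)) for nm in tau2}
    store_dev = np.empty(S)

    s_idx = 0
    for it in range(options.iterations):
        for l in range(N_CATEGORIES):
            others = [k for k in range(N_CATEGORIES) if k != l]
            C = np.logaddexp(np.logaddexp(eta[others[0]], eta[others[1]]), 0.0)
            kappa = yind[l] - 0.5
            if method == "pg":
                omega = polya_gamma(eta[l] - C, rng)
            for t in terms:
                prec = (t.fixed_prec if t.K is None
                        else t.K / tau2[t.name][l])
                off = eta[l] - fitted[t.name][l] - C
                if method == "pg":
                    if t.group_idx is not None:
                        theta = _pg_group_draw(t.group_idx, t.X.shape[1],
                                               omega, kappa, off, prec, rng)
                    else:
                        theta = _pg_block_draw(t.X, omega, kappa, off, prec, rng)
                else:
                    theta = _iwls_block_draw(t.X, yind[l], off, prec,
                                             coef[t.name][l], rng)
                coef[t.name][l] = theta
                if t.group_idx is not None:
                    fitted[t.name][l] = theta[t.group_idx]
                else:
                    fitted[t.name][l] = t.X @ theta
                eta[l] = off + C + fitted[t.name][l]
            # identifiability recentring, absorbed into the intercept
            for t in terms:
                if t.center == "fitted":
                    c = fitted[t.name][l].mean()
                elif t.center == "coef":
                    c = coef[t.name][l].mean()
                else:
                    continue
                coef[t.name][l] -= c
                fitted[t.name][l] -= c  # 0/1 indicator rows and unit-sum
                # B-spline rows both shift fitted values by exactly c
                coef["fixed"][l][0] += c
                fitted["fixed"][l] += c
        for t in terms:
            if t.sample_tau2:
                a, b = priors.ab(t.name)
                for l in range(N_CATEGORIES):
                    beta = coef[t.name][l]
                    quad = float(beta @ t.K @ beta)
                    tau2[t.name][l] = _ig_draw(a + t.rank / 2.0,
                                               b + max(quad, 0.0) / 2.0, rng)
        if not np.all(np.isfinite(eta)):
            raise RuntimeError(f"non-finite sampler state at iteration {it}")
        if it >= options.burnin and (it - options.burnin) % options.thin == 0:
            for t in terms:
                store_coef[t.name][s_idx] = coef[t.name]
            for nm in tau2:
                store_tau2[nm][s_idx] = tau2[nm]
            store_dev[s_idx] = deviance(eta.T, y)
            s_idx += 1

    assert s_idx == S
    out = PosteriorSamples(
        model=model, coef=store_coef, tau2=store_tau2, deviance=store_dev,
        fixed_labels=tuple(fixed_labels), region_ids=region_ids,
        spline=spline_meta, options=options, priors=priors, method=method,
        centered=center)
    out.final_state = {"coef": {nm: v.copy() for nm, v in coef.items()},
                       "tau2": {nm: v.copy() for nm, v in tau2.items()}}
    return out


def _pg_block_draw(X, omega, kappa, offset, prior_prec, rng):
    """Gaussian full-conditional draw of one coefficient block given omega."""
    P = X.T @ (X * omega[:, None]) + prior_prec
    b = X.T @ (kappa - omega * offset)
    L = cholesky(P, lower=True)
    mean = solve_triangular(L.T, solve_triangular(L, b, lower=True), lower=False)
    z = rng.standard_normal(len(b))
    return mean + solve_triangular(L.T, z, lower=False)


def _pg_group_draw(idx, p, omega, kappa, offset, prior_prec, rng):
    """Same full conditional when X is a 0/1 group indicator: X'ΩX is
    diagonal and both moments reduce to per-group sums."""
    P = np.diag(np.bincount(idx, weights=omega, minlength=p)) + prior_prec
    b = np.bincount(idx, weights=kappa - omega * offset, minlength=p)
    L = cholesky(P, lower=True)
    mean = solve_triangular(L.T, solve_triangular(L, b, lower=True), lower=False)
    z = rng.standard_normal(p)
    return mean + solve_triangular(L.T, z, lower=False)


def _iwls_block_draw(X, ystar, offset, prior_prec, theta_cur, rng):
    """Metropolis-Hastings step with an IWLS Gaussian proposal."""
    def proposal(theta0):
        psi0 = X @ theta0 + offset
        p0 = expit(psi0)
        w = p0 * (1.0 - p0) + 1e-6
        work = psi0 + (ystar - p0) / w - offset
        P = X.T @ (X * w[:, None]) + prior_prec
        L = cholesky(P, lower=True)
        b = X.T @ (w * work)
        mean = solve_triangular(L.T, solve_triangular(L, b, lower=True),
                                lower=False)
        return mean, L

    def log_q(x, mean, L):
        r = L.T @ (x - mean)
        return float(np.sum(np.log(np.diag(L))) - 0.5 * r @ r)

    def log_target(theta):
        psi = X @ theta + offset
        ll = float(np.sum(ystar * psi - np.logaddexp(0.0, psi)))
        return ll - 0.5 * float(theta @ prior_prec @ theta)

    mean_f, L_f = proposal(theta_cur)
    prop = mean_f + solve_triangular(L_f.T, rng.standard_normal(len(mean_f)),
                                     lower=False)
    mean_b, L_b = proposal(prop)
    log_alpha = (log_target(prop) - log_target(theta_cur)
                 + log_q(theta_cur, mean_b, L_b) - log_q(prop, mean_f, L_f))
    if np.log(rng.random()) < log_alpha:
        return prop
    return theta_cur


# ---------------------------------------------------------------------------
# convergence diagnostics
# ---------------------------------------------------------------------------

def diagnostics(samples: "PosteriorSamples | Mapping[str, np.ndarray]",
                rhat_threshold: float = 1.1) -> pd.DataFrame:
    """Effective sample size and split-chain R-hat per scalar parameter.

    Accepts a :class:`PosteriorSamples` (fixed effects and variances are
    diagnosed) or a mapping of name -> 1-D chain. Constant chains are
    reported as degenerate (flagged) rather than raising.
    """
    import arviz as az

    chains: dict[str, np.ndarray] = {}
    if isinstance(samples, PosteriorSamples):
        for l in range(N_CATEGORIES):
            arr = samples.coef["fixed"][:, l, :]
            for j, lab in enumerate(samples.fixed_labels):
                chains[f"cat{l+1}.{lab}"] = arr[:, j]
            for nm, t in samples.tau2.items():
                chains[f"cat{l+1}.tau2_{nm}"] = t[:, l]
    else:
        chains = {k: np.asarray(v, dtype=float) for k, v in samples.items()}
    first = next(iter(chains.values()))
    if len(first) < 100:
        raise ValueError("diagnostics need at least 100 stored draws")
    rows = []
    for name, x in chains.items():
        if np.ptp(x) == 0:
            rows.append({"param": name, "ess": float("nan"),
                         "rhat": float("nan"), "flag": True,
                         "note": "degenerate (constant chain)"})
            continue
        ess = float(az.ess(x[None, :], method="mean"))
        half = (len(x) // 2) * 2
        rhat = float(az.rhat(x[:half].reshape(2, -1)))  # split-chain R-hat
        flag = (not np.isfinite(rhat)) or rhat > rhat_threshold
        rows.append({"param": name, "ess": ess, "rhat": rhat,
                     "flag": bool(flag), "note": ""})
    return pd.DataFrame(rows)
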