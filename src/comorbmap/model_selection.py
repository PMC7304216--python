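"""Candidate predictor forms M1-M6 and DIC model comparison.

M1: fixed effects only.            M2: fixed + smooth f(age).
M3: structured + unstructured.     M4: fixed + structured + unstructured.
M5: fixed + smooth + structured.   M6: fixed + smooth + structured + unstructured.

Every model keeps a per-category intercept; "fixed" toggles the covariate
dummies beyond it.

DIC uses the classic plug-in form: pD = Dbar - D(theta_bar) with posterior
means of the coefficients (not of the probabilities), DIC = Dbar + pD.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
import pandas as pd

from .data_model import Dataset, RegionGraph
from .design import category_probabilities

if TYPE_CHECKING:  # pragma: no cover
    from .inference import MCMCOptions, PosteriorSamples, PriorSpec


@dataclass(frozen=True)
class ModelSpec:
    """Which terms enter the category predictors."""

    fixed: bool
    smooth: bool
    structured: bool
    unstructured: bool
    name: str = "custom"

    @property
    def needs_graph(self) -> bool:
        return self.structured or self.unstructured


MODELS: dict[str, ModelSpec] = {
    "M1": ModelSpec(True, False, False, False, "M1"),
    "M2": ModelSpec(True, True, False, False, "M2"),
    "M3": ModelSpec(False, False, True, True, "M3"),
    "M4": ModelSpec(True, False, True, True, "M4"),
    "M5": ModelSpec(True, True, True, False, "M5"),
    "M6": ModelSpec(True, True, True, True, "M6"),
}


def model_spec(name: str) -> ModelSpec:
    try:
        return MODELS[name.upper()]
    except KeyError:
        raise ValueError(f"unknown model form {name!r}; expected M1..M6") from None


@dataclass(frozen=True)
class DICResult:
    dbar: float          # posterior mean deviance
    d_at_mean: float     # deviance at posterior means of the coefficients
    pd: float            # effective number of parameters, Dbar - D(theta_bar)
    dic: float           # Dbar + pD

    def __post_init__(self):
        assert abs(self.dic - (self.d_at_mean + 2 * self.pd)) < 1e-6


def deviance(eta: np.ndarray, outcomes: np.ndarray) -> float:
    """-2 log multinomial likelihood of the observed categories.

    ``eta`` is (n, 3) (categories 1..3; baseline predictor is 0),
    ``outcomes`` the observed category codes 0..3. Probabilities below
    1e-300 are clamped (with a warning) to keep the result finite.
    """
    pi = category_probabilities(eta)
    p_obs = pi[np.arange(len(outcomes)), np.asarray(outcomes, dtype=int)]
    if np.any(p_obs < 1e-300):
        warnings.warn("observed-category probability clamped at 1e-300",
                      stacklevel=2)
        p_obs = np.maximum(p_obs, 1e-300)
    return float(-2.0 * np.sum(np.log(p_obs)))


def dic(samples: "PosteriorSamples", dataset: Dataset,
        graph: RegionGraph | None = None) -> DICResult:
    """DIC from stored per-draw deviances and the plug-in posterior mean.

    The plug-in deviance re-evaluates the predictor at the posterior mean of
    every coefficient block, rebuilding the designs from ``dataset``.
    """
    if samples.n_draws < 2:
        raise ValueError("DIC requires at least 2 stored draws")
    dbar = float(np.mean(samples.deviance))
    eta_bar = samples.predict_eta(dataset, graph, at_mean=True)
    d_at_mean = deviance(eta_bar, dataset.records["outcome"].to_numpy())
    p_d = dbar - d_at_mean
    return DICResult(dbar=dbar, d_at_mean=d_at_mean, pd=p_d, dic=dbar + p_d)


def compare(dataset: Dataset, graph: RegionGraph | None,
            priors: "PriorSpec | None" = None,
            options: "MCMCOptions | None" = None,
            models: Sequence[str] = ("M1", "M2", "M3", "M4", "M5", "M6"),
            method: str = "pg") -> pd.DataFrame:
    """Fit each candidate model and tabulate Dbar, D(theta_bar), pD and DIC.

    Returns one row per model; the DIC-minimal row is flagged in a
    ``best`` column — the choice among near-ties is the analyst's.
    """
    from .inference import MCMCOptions, PriorSpec, fit

    priors = priors or PriorSpec()
    options = options or MCMCOptions()
    rows = []
    for name in models:
        spec = model_spec(name)
        s = fit(dataset, graph if spec.needs_graph else graph, spec,
                priors=priors, options=options, method=method)
        r = dic(s, dataset, graph)
        rows.append({"model": spec.name, "deviance_mean": r.dbar,
                     "deviance_at_mean": r.d_at_mean, "pD": r.pd, "DIC": r.dic})
    out = pd.DataFrame(rows)
    out["best"] = out["DIC"] == out["DIC"].min()
    return out
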