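"""Descriptive tables and posterior summaries.

Covers: covariate x outcome cross-tabulations with Pearson chi-square tests;
posterior odds-ratio tables with 95% credible intervals per non-reference
category; three-class spatial significance maps from the structured effect's
95% interval; and posterior age-curves with nested 80%/95% pointwise bands.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import chi2_contingency

from .data_model import CATEGORY_LABELS, Dataset
from .inference import N_CATEGORIES, PosteriorSamples

#: published cross-tabulation counts (2016 Ethiopia DHS, N = 8742): covariate
#: level x outcome category (0..3 illnesses). Re-analysed by the descriptive
#: stage without access to the restricted microdata.
PUBLISHED_CROSSTABS: dict[str, dict[str, tuple[int, int, int, int]]] = {
    "sex": {"male": (3222, 683, 400, 149), "female": (3173, 579, 394, 142)},
    "anemia": {"anemic": (6216, 1236, 779, 289), "non_anemic": (179, 26, 15, 2)},
    "breastfeeding": {"no": (2114, 432, 261, 80), "yes": (4281, 830, 533, 211)},
    "toilet": {"flush": (250, 52, 37, 11), "latrine": (3253, 669, 380, 130),
               "no_facility": (2892, 541, 377, 150)},
    "delivery": {"home": (4231, 771, 465, 176),
                 "health_center": (2164, 491, 329, 115)},
    "working": {"no": (4680, 891, 552, 189), "yes": (1715, 371, 242, 102)},
    "household_size": {"1-5": (2747, 610, 361, 136), "6-10": (3457, 607, 407, 146),
                       "over_10": (191, 45, 26, 9)},
    "education": {"none": (4160, 730, 495, 181), "primary": (1578, 370, 230, 86),
                  "secondary_plus": (657, 162, 69, 24)},
    "birth_order": {"first": (1203, 303, 160, 60), "2-3": (2071, 391, 262, 83),
                    "4_plus": (3121, 568, 372, 148)},
    "water": {"piped": (848, 204, 122, 36), "public_tap": (2943, 549, 366, 123),
              "protected_spring": (510, 85, 66, 31), "other": (2094, 424, 240, 101)},
}


@dataclass(frozen=True)
class CrosstabResult:
    """Level x outcome counts with row percentages and a Pearson test."""

    covariate: str
    levels: tuple[str, ...]
    counts: np.ndarray        # levels x 4
    row_percent: np.ndarray   # levels x 4, rows sum to 100
    chi2: float
    df: int
    p_value: float


def crosstab_from_counts(covariate: str, levels, counts) -> CrosstabResult:
    """Pearson chi-square on an explicit level x category count table."""
    counts = np.asarray(counts, dtype=float)
    if counts.min() < 0:
        raise ValueError("negative count")
    row = counts.sum(axis=1)
    col = counts.sum(axis=0)
    if (row == 0).any():
        bad = levels[int(np.argmax(row == 0))]
        raise ValueError(f"zero margin for level {bad!r}")
    if (col == 0).any():
        raise ValueError(f"zero margin for outcome category "
                         f"{int(np.argmax(col == 0))}")
    res = chi2_contingency(counts, correction=False)
    pct = 100.0 * counts / row[:, None]
    return CrosstabResult(covariate=covariate, levels=tuple(levels),
                          counts=counts.astype(int), row_percent=pct,
                          chi2=float(res.statistic), df=int(res.dof),
                          p_value=float(res.pvalue))


def crosstab_chisq(dataset: Dataset, covariate: str) -> CrosstabResult:
    """Covariate x outcome cross-tabulation from child-level records."""
    cov = dataset.schema[covariate]
    df = dataset.records
    counts = np.array([[int(((df[covariate] == lev) & (df["outcome"] == l)).sum())
                        for l in range(4)] for lev in cov.levels])
    return crosstab_from_counts(covariate, cov.levels, counts)


def descriptive_table(dataset: Dataset) -> pd.DataFrame:
    """All-covariate descriptive table: counts, row %, chi-square p (3 dp)."""
    rows = []
    for cov in dataset.schema:
        ct = crosstab_chisq(dataset, cov.name)
        for i, lev in enumerate(ct.levels):
            row = {"covariate": cov.name, "level": lev}
            for l in range(4):
                row[f"n_{l}"] = int(ct.counts[i, l])
                row[f"pct_{l}"] = round(float(ct.row_percent[i, l]), 1)
            row["p_value"] = round(ct.p_value, 3) if i == 0 else np.nan
            rows.append(row)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# posterior summaries
# ---------------------------------------------------------------------------

def or_summary(samples: PosteriorSamples) -> pd.DataFrame:
    """Posterior odds ratios exp(beta) with 95% credible intervals.

    Point estimate is the posterior mean of exp(beta) ("or_mean", primary);
    exp of the posterior mean ("or_exp_mean") is also reported. An effect is
    flagged significant when the (2.5%, 97.5%) interval of exp(beta)
    excludes 1.
    """
    if samples.n_draws < 100:
        raise ValueError("odds-ratio summary needs at least 100 stored draws")
    rows = []
    for l in range(1, N_CATEGORIES + 1):
        draws = samples.fixed_draws(l)
        ors = np.exp(draws)
        lo, hi = np.quantile(ors, [0.025, 0.975], axis=0)
        for j, lab in enumerate(samples.fixed_labels):
            rows.append({
                "category": CATEGORY_LABELS[l],
                "term": lab,
                "or_mean": ors[:, j].mean(),
                "or_exp_mean": np.exp(draws[:, j].mean()),
                "ci_2.5": lo[j],
                "ci_97.5": hi[j],
                "significant": bool(lo[j] > 1.0 or hi[j] < 1.0),
            })
    return pd.DataFrame(rows)


def spatial_significance(samples: PosteriorSamples,
                         kind: str = "str") -> pd.DataFrame:
    """Three-class map: per region/category, +1 if the 2.5% posterior
    quantile of the structured effect is above 0, -1 if the 97.5% quantile is
    below 0, else 0."""
    if kind not in samples.coef:
        raise ValueError(f"model has no {kind!r} spatial term")
    rows = []
    for l in range(1, N_CATEGORIES + 1):
        draws = samples.spatial_draws(l, kind)
        lo, hi = np.quantile(draws, [0.025, 0.975], axis=0)
        mean = draws.mean(axis=0)
        for r, region in enumerate(samples.region_ids):
            cls = 1 if lo[r] > 0 else (-1 if hi[r] < 0 else 0)
            rows.append({"category": CATEGORY_LABELS[l], "region_id": region,
                         "effect_mean": mean[r], "ci_2.5": lo[r],
                         "ci_97.5": hi[r], "class": cls})
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class SmoothCurve:
    """Posterior age-curve: mean with nested pointwise 80% and 95% bands."""

    grid: np.ndarray
    mean: np.ndarray      # (g, 3)
    lo95: np.ndarray
    hi95: np.ndarray
    lo80: np.ndarray
    hi80: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        frames = []
        for l in range(N_CATEGORIES):
            frames.append(pd.DataFrame({
                "category": CATEGORY_LABELS[l + 1], "age_months": self.grid,
                "mean": self.mean[:, l], "lo95": self.lo95[:, l],
                "hi95": self.hi95[:, l], "lo80": self.lo80[:, l],
                "hi80": self.hi80[:, l]}))
        return pd.concat(frames, ignore_index=True)


def smooth_bands(samples: PosteriorSamples,
                 grid: np.ndarray | None = None) -> SmoothCurve:
    """Pointwise posterior mean and central 80%/95% bands of f_l(age)."""
    if "smooth" not in samples.coef:
        raise ValueError("model has no smooth term")
    if grid is None:
        sp = samples.spline
        grid = np.linspace(sp["x_min"], sp["x_max"], 60)
    grid = np.asarray(grid, dtype=float)
    mean = np.empty((len(grid), N_CATEGORIES))
    q = {lvl: np.empty((len(grid), N_CATEGORIES))
         for lvl in ("lo95", "hi95", "lo80", "hi80")}
    for l in range(1, N_CATEGORIES + 1):
        draws = samples.smooth_draws(l, grid)     # may raise on out-of-range
        mean[:, l - 1] = draws.mean(axis=0)
        q["lo95"][:, l - 1], q["hi95"][:, l - 1] = np.quantile(
            draws, [0.025, 0.975], axis=0)
        q["lo80"][:, l - 1], q["hi80"][:, l - 1] = np.quantile(
            draws, [0.10, 0.90], axis=0)
    return SmoothCurve(grid=grid, mean=mean, **q)
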