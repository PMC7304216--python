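"""Getis-Ord Gi* hotspot/coldspot detection at survey-cluster level.

For cluster i with weights w_ij (self-weight included — the * variant),

    Gi* z_i = (sum_j w_ij x_j - xbar W_i)
              / (S sqrt[(n sum_j w_ij^2 - W_i^2) / (n - 1)])

with W_i = sum_j w_ij and xbar, S the global mean and *population* SD of the
cluster values (cluster i included). Under the null the z's are compared to
the standard Gaussian; two-sided p < alpha with z > 0 marks a hotspot
("high"), z < 0 a coldspot ("low").

Default weights: binary k-nearest-neighbour (k = 8) by great-circle
distance plus the self-weight; a fixed distance band is also available.
Default cluster value: mean number of concurrent illnesses per child.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import Dataset, haversine_km

VALUE_KINDS = ("mean_count", "any_illness", "multi_illness")


def cluster_values(dataset: Dataset, kind: str = "mean_count") -> pd.DataFrame:
    """Per-cluster comorbidity intensity with region and coordinates.

    ``mean_count``: mean outcome category (0-3) among the cluster's children;
    ``any_illness``: proportion with >= 1 illness; ``multi_illness``:
    proportion with >= 2 (the comorbid children proper).
    """
    if kind not in VALUE_KINDS:
        raise ValueError(f"kind must be one of {VALUE_KINDS}")
    df = dataset.records
    g = df.groupby("cluster_id", sort=False)
    if kind == "mean_count":
        val = g["outcome"].mean()
    elif kind == "any_illness":
        val = g["outcome"].apply(lambda s: float(np.mean(s >= 1)))
    else:
        val = g["outcome"].apply(lambda s: float(np.mean(s >= 2)))
    region = g["region_id"].first()
    out = pd.DataFrame({"value": val, "region_id": region})
    out = out.join(dataset.cluster_coords)
    if len(out) < 2:
        raise ValueError("hotspot analysis needs at least 2 clusters")
    return out


def knn_weights(lon: np.ndarray, lat: np.ndarray, k: int = 8) -> np.ndarray:
    """Binary k-nearest-neighbour weight matrix (haversine), self-weight 1.

    Not symmetrized: Gi* does not require symmetric weights.
    """
    n = len(lon)
    if k >= n:
        raise ValueError("k must be smaller than the number of clusters")
    D = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    np.fill_diagonal(D, np.inf)
    W = np.zeros((n, n))
    nearest = np.argpartition(D, k, axis=1)[:, :k]
    rows = np.repeat(np.arange(n), k)
    W[rows, nearest.ravel()] = 1.0
    np.fill_diagonal(W, 1.0)
    return W


def distance_band_weights(lon: np.ndarray, lat: np.ndarray,
                          band_km: float) -> np.ndarray:
    """Binary weights within a fixed great-circle distance, self included."""
    D = haversine_km(lon[:, None], lat[:, None], lon[None, :], lat[None, :])
    return (D <= band_km).astype(float)


def gi_star(values: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Vectorized Gi* z-scores. All-equal values give z = 0 by convention."""
    x = np.asarray(values, dtype=float)
    W = np.asarray(weights, dtype=float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 locations")
    if W.shape != (n, n):
        raise ValueError("weights must be n x n")
    if (W < 0).any():
        raise ValueError("weights must be non-negative")
    row_tot = W.sum(axis=1)
    if (row_tot <= 0).any():
        raise ValueError("a location has all-zero weights")
    xbar = x.mean()
    s = x.std(ddof=0)
    if s == 0:
        import warnings
        warnings.warn("all values equal: Gi* z-scores set to 0", stacklevel=2)
        return np.zeros(n)
    num = W @ x - xbar * row_tot
    denom = s * np.sqrt((n * (W ** 2).sum(axis=1) - row_tot ** 2) / (n - 1))
    return num / denom


@dataclass(frozen=True)
class HotspotResult:
    """Per-cluster Gi* z, two-sided Gaussian p, and high/low/insignificant class."""

    table: pd.DataFrame  # cluster_id index; value, region_id, lon, lat, z, p, cls
    alpha: float

    def by_region(self) -> pd.DataFrame:
        return tabulate_by_region(self)


def classify(z: np.ndarray, alpha: float = 0.05,
             fdr: bool = False) -> tuple[np.ndarray, np.ndarray]:
    """Two-sided Gaussian p-values and hotspot classes for Gi* z-scores.

    ``fdr=True`` applies Benjamini-Hochberg before thresholding (the default
    mirrors the raw p < 0.05 convention of typical hotspot maps).
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    z = np.asarray(z, dtype=float)
    p = 2.0 * norm.sf(np.abs(z))
    p_test = p
    if fdr:
        from statsmodels.stats.multitest import multipletests
        p_test = multipletests(p, method="fdr_bh")[1]
    cls = np.where(p_test < alpha, np.where(z > 0, "high", "low"),
                   "insignificant")
    cls[z == 0] = "insignificant"
    return p, cls


def hotspots(dataset: Dataset, kind: str = "mean_count", k: int = 8,
             alpha: float = 0.05, band_km: float | None = None,
             fdr: bool = False) -> HotspotResult:
    """End-to-end cluster-level Gi* analysis on a dataset."""
    cv = cluster_values(dataset, kind)
    lon = cv["lon"].to_numpy()
    lat = cv["lat"].to_numpy()
    if band_km is not None:
        W = distance_band_weights(lon, lat, band_km)
    else:
        W = knn_weights(lon, lat, k=k)
    z = gi_star(cv["value"].to_numpy(), W)
    p, cls = classify(z, alpha=alpha, fdr=fdr)
    table = cv.copy()
    table["z"] = z
    table["p"] = p
    table["cls"] = cls
    return HotspotResult(table=table, alpha=alpha)


def tabulate_by_region(result: HotspotResult,
                       dataset: Dataset | None = None) -> pd.DataFrame:
    """Region-level counts of overall / high / low / insignificant clusters."""
    t = result.table
    if t["region_id"].isna().any():
        raise ValueError("unmapped cluster (missing region)")
    rows = []
    for region, sub in t.groupby("region_id", sort=False):
        rows.append({
            "region_id": region,
            "overall": len(sub),
            "high": int((sub["cls"] == "high").sum()),
            "low": int((sub["cls"] == "low").sum()),
            "insignificant": int((sub["cls"] == "insignificant").sum()),
        })
    out = pd.DataFrame(rows)
    assert (out["high"] + out["low"] + out["insignificant"]).equals(out["overall"])
    return out
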