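"""Design and penalty objects for the structured additive predictor.

The predictor for outcome category l (category 0 is the baseline with
eta identically 0) is

    eta_l = H beta_l + f_l(age) + f_str(region) + f_unstr(region)

built from: a dummy-coded fixed-effect design H (reference levels omitted,
intercept first), a cubic B-spline basis for the age smooth with a
second-order random-walk (RW2) penalty D2'D2, and the intrinsic-MRF structure
matrix over regions (diagonal = neighbor counts, -1 between neighbors).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.interpolate import BSpline

from .data_model import CovariateSchema, Dataset, RegionGraph


@dataclass(frozen=True)
class FixedDesign:
    """Dummy-coded fixed-effect matrix with an intercept as first column."""

    matrix: np.ndarray            # n x p
    labels: tuple[str, ...]       # "intercept", then "covariate=level"

    @property
    def p(self) -> int:
        return self.matrix.shape[1]


@dataclass(frozen=True)
class SplineBasis:
    """Equidistant B-spline basis with an RW2 difference penalty.

    The penalty is D2'D2 (D2 the second-difference operator on the m
    coefficients), rank m-2: constants and linear trends in the coefficient
    sequence are unpenalized, matching a second-order random-walk prior.
    """

    knots: np.ndarray             # full knot vector incl. boundary extension
    degree: int
    matrix: np.ndarray            # n x m
    penalty: np.ndarray           # m x m
    x_min: float
    x_max: float

    @property
    def m(self) -> int:
        return self.matrix.shape[1]

    @property
    def penalty_rank(self) -> int:
        return self.m - 2

    def evaluate(self, x: np.ndarray) -> np.ndarray:
        """Basis matrix at new points (must lie within the fitted range)."""
        x = np.asarray(x, dtype=float)
        if x.min() < self.x_min or x.max() > self.x_max:
            raise ValueError(
                f"evaluation points outside fitted range "
                f"[{self.x_min}, {self.x_max}]"
            )
        return BSpline.design_matrix(x, self.knots, self.degree,
                                     extrapolate=False).toarray()


@dataclass(frozen=True)
class MRFPrecision:
    """Intrinsic-MRF structure matrix: K[s,s]=N_s, K[s,r]=-1 for neighbors."""

    matrix: np.ndarray            # R x R
    region_ids: tuple[str, ...]

    @property
    def rank(self) -> int:
        # rank R - c for c connected components; R-1 when connected
        return int(np.linalg.matrix_rank(self.matrix))


def build_fixed_design(dataset: Dataset,
                       schema: CovariateSchema | None = None) -> FixedDesign:
    """Dummy-code the covariates: one 0/1 column per non-reference level.

    Column order is deterministic: intercept, then schema order, then the
    declared level order within each covariate.
    """
    schema = schema or dataset.schema
    n = dataset.n
    cols = [np.ones(n)]
    labels = ["intercept"]
    for cov in schema:
        values = dataset.records[cov.name].to_numpy()
        any_nonref = False
        for level in cov.nonreference_levels:
            col = (values == level).astype(float)
            if col.sum() == 0:
                warnings.warn(
                    f"covariate {cov.name!r}: level {level!r} unobserved "
                    f"(all-zero design column)", stacklevel=2)
            any_nonref = any_nonref or col.any()
            cols.append(col)
            labels.append(f"{cov.name}={level}")
        if not any_nonref:
            warnings.warn(f"covariate {cov.name!r} is all-reference", stacklevel=2)
    X = np.column_stack(cols)
    # duplicate (collinear) dummy columns indicate a degenerate schema
    _, idx = np.unique(X.T, axis=0, return_index=True)
    if len(idx) != X.shape[1]:
        dup = sorted(set(range(X.shape[1])) - set(idx))
        raise ValueError(f"collinear duplicate design columns: "
                         f"{[labels[i] for i in dup]}")
    return FixedDesign(matrix=X, labels=tuple(labels))


def bspline_basis(x: np.ndarray, n_interior_knots: int = 20,
                  degree: int = 3) -> SplineBasis:
    """Cubic B-spline basis on equidistant knots over the range of ``x``.

    ``m = n_interior_knots + degree + 1`` basis functions; rows sum to one
    (partition of unity). The returned penalty is the RW2 matrix D2'D2.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2 or np.ptp(x) == 0:
        raise ValueError("x must be non-degenerate (at least two distinct values)")
    m = n_interior_knots + degree + 1
    if m < degree + 1:
        raise ValueError("basis size must be at least degree + 1")
    lo, hi = float(x.min()), float(x.max())
    inner = np.linspace(lo, hi, n_interior_knots + 2)
    step = inner[1] - inner[0]
    knots = np.concatenate([
        lo - step * np.arange(degree, 0, -1),
        inner,
        hi + step * np.arange(1, degree + 1),
    ])
    B = BSpline.design_matrix(x, knots, degree, extrapolate=False).toarray()
    D2 = np.diff(np.eye(m), n=2, axis=0)
    K = D2.T @ D2
    K = (K + K.T) / 2  # exact symmetry
    return SplineBasis(knots=knots, degree=degree, matrix=B, penalty=K,
                       x_min=lo, x_max=hi)


def mrf_precision(graph: RegionGraph) -> MRFPrecision:
    """Structure matrix of the intrinsic CAR prior on region effects.

    f' K f equals the sum of squared differences over neighbouring pairs;
    rows sum to zero; rank R-1 for a connected graph.
    """
    R = graph.n_regions
    K = np.zeros((R, R))
    pos = {r: i for i, r in enumerate(graph.region_ids)}
    for r in graph.region_ids:
        i = pos[r]
        nb = graph.neighbors.get(r, frozenset())
        K[i, i] = len(nb)
        for s in nb:
            K[i, pos[s]] = -1.0
    assert np.array_equal(K, K.T)
    return MRFPrecision(matrix=K, region_ids=graph.region_ids)


def region_indicator(dataset: Dataset, graph: RegionGraph) -> np.ndarray:
    """n x R 0/1 incidence of records onto graph-ordered regions."""
    dataset.validate_against(graph)
    pos = {r: i for i, r in enumerate(graph.region_ids)}
    idx = dataset.records["region_id"].map(pos).to_numpy()
    Z = np.zeros((dataset.n, graph.n_regions))
    Z[np.arange(dataset.n), idx] = 1.0
    return Z


def category_probabilities(eta: np.ndarray) -> np.ndarray:
    """Baseline-category logit probabilities over the four outcome classes.

    ``eta`` is (n, 3) — predictors for categories 1..3; the baseline
    (category 0) predictor is identically 0. Computed with a max-shift so
    |eta| up to ~700 stays finite.
    """
    eta = np.atleast_2d(np.asarray(eta, dtype=float))
    if eta.shape[1] != 3:
        raise ValueError("eta must have three columns (categories 1..3)")
    if not np.all(np.isfinite(eta)):
        raise ValueError("non-finite predictor")
    full = np.concatenate([np.zeros((eta.shape[0], 1)), eta], axis=1)
    shift = full.max(axis=1, keepdims=True)
    ex = np.exp(full - shift)
    return ex / ex.sum(axis=1, keepdims=True)
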