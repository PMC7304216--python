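"""Core data types and file I/O for child illness records and region adjacency.

The unit of observation is a child with a four-category outcome — the number
(0–3) of illnesses (diarrhea, fever, cough) experienced concurrently in the
survey recall window — plus categorical risk factors, age in months, and
membership in a georeferenced survey cluster nested within a region.

Regions form an adjacency graph (two regions are neighbours when they share a
boundary); the graph drives the intrinsic Markov-random-field spatial prior.
"""

from __future__ import annotations

import io
import json
import logging
import math
import sys
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

OUTCOME_CATEGORIES = (0, 1, 2, 3)
CATEGORY_LABELS = {
    0: "none of the illnesses",
    1: "one illness",
    2: "two illnesses",
    3: "three illnesses",
}

#: Earth radius in km, for great-circle distances between cluster points.
EARTH_RADIUS_KM = 6371.0088


def haversine_km(lon1, lat1, lon2, lat2):
    """Great-circle distance in km between WGS84 points (vectorized)."""
    lon1, lat1, lon2, lat2 = (np.radians(np.asarray(a, dtype=float))
                              for a in (lon1, lat1, lon2, lat2))
    dlon = lon2 - lon1
    dlat = lat2 - lat1
    h = np.sin(dlat / 2) ** 2 + np.cos(lat1) * np.cos(lat2) * np.sin(dlon / 2) ** 2
    return 2 * EARTH_RADIUS_KM * np.arcsin(np.sqrt(h))


# ---------------------------------------------------------------------------
# Covariate schema
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Covariate:
    """A categorical risk factor: its level set and declared reference level."""

    name: str
    levels: tuple[str, ...]
    reference: str

    def __post_init__(self):
        if self.reference not in self.levels:
            raise ValueError(
                f"covariate {self.name!r}: reference {self.reference!r} "
                f"not among levels {self.levels}"
            )
        if len(set(self.levels)) != len(self.levels):
            raise ValueError(f"covariate {self.name!r}: duplicate levels")

    @property
    def nonreference_levels(self) -> tuple[str, ...]:
        return tuple(l for l in self.levels if l != self.reference)


@dataclass(frozen=True)
class CovariateSchema:
    """Ordered covariate declaration used for validation and design coding."""

    covariates: tuple[Covariate, ...]

    @property
    def names(self) -> tuple[str, ...]:
        return tuple(c.name for c in self.covariates)

    def __getitem__(self, name: str) -> Covariate:
        for c in self.covariates:
            if c.name == name:
                return c
        raise KeyError(name)

    def __iter__(self) -> Iterator[Covariate]:
        return iter(self.covariates)

    def __len__(self) -> int:
        return len(self.covariates)


def default_schema() -> CovariateSchema:
    """The DHS risk-factor scheme used throughout: ten categorical covariates.

    Reference levels follow the convention of the fitted odds-ratio tables
    (male / anemic / not breastfed / no toilet facility / health-center
    delivery / mother not working / 1-5 household members / no education /
    first birth / piped water).
    """
    return CovariateSchema((
        Covariate("sex", ("male", "female"), "male"),
        Covariate("anemia", ("anemic", "non_anemic"), "anemic"),
        Covariate("breastfeeding", ("no", "yes"), "no"),
        Covariate("toilet", ("no_facility", "latrine", "flush"), "no_facility"),
        Covariate("delivery", ("health_center", "home"), "health_center"),
        Covariate("working", ("no", "yes"), "no"),
        Covariate("household_size", ("1-5", "6-10", "over_10"), "1-5"),
        Covariate("education", ("none", "primary", "secondary_plus"), "none"),
        Covariate("birth_order", ("first", "2-3", "4_plus"), "first"),
        Covariate("water", ("piped", "public_tap", "protected_spring", "other"),
                  "piped"),
    ))


# ---------------------------------------------------------------------------
# Region adjacency graph
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RegionGraph:
    """Undirected region adjacency: symmetric, no self-loops.

    ``region_ids`` fixes the ordering used for every region-indexed vector
    (spatial effects, MRF precision rows).
    """

    region_ids: tuple[str, ...]
    neighbors: Mapping[str, frozenset[str]]

    def __post_init__(self):
        ids = set(self.region_ids)
        if len(ids) != len(self.region_ids):
            raise ValueError("duplicate region ids")
        for r, nb in self.neighbors.items():
            if r not in ids:
                raise ValueError(f"neighbors declared for unknown region {r!r}")
            if r in nb:
                raise ValueError(f"self-loop at region {r!r}")
            for s in nb:
                if s not in ids:
                    raise ValueError(f"region {r!r} lists unknown neighbor {s!r}")
                if r not in self.neighbors.get(s, frozenset()):
                    raise ValueError(
                        f"asymmetric adjacency: {r!r} lists {s!r} but not vice versa"
                    )
        isolated = [r for r in self.region_ids
                    if not self.neighbors.get(r, frozenset())]
        if isolated:
            logger.warning("isolated regions (no neighbors): %s", isolated)

    @classmethod
    def from_edges(cls, region_ids: Sequence[str],
                   edges: Iterable[tuple[str, str]]) -> "RegionGraph":
        nb: dict[str, set[str]] = {r: set() for r in region_ids}
        for a, b in edges:
            if a == b:
                raise ValueError(f"self-loop at region {a!r}")
            nb[a].add(b)
            nb[b].add(a)
        return cls(tuple(region_ids), {r: frozenset(s) for r, s in nb.items()})

    @property
    def n_regions(self) -> int:
        return len(self.region_ids)

    def neighbor_counts(self) -> dict[str, int]:
        """N_s: number of adjacent regions, per region."""
        return {r: len(self.neighbors.get(r, frozenset())) for r in self.region_ids}

    def index(self, region_id: str) -> int:
        return self.region_ids.index(region_id)

    def edges(self) -> list[tuple[str, str]]:
        """Undirected edges, each once, in region order."""
        pos = {r: i for i, r in enumerate(self.region_ids)}
        out = []
        for r in self.region_ids:
            for s in sorted(self.neighbors.get(r, frozenset()), key=pos.__getitem__):
                if pos[r] < pos[s]:
                    out.append((r, s))
        return out

    def is_connected(self) -> bool:
        if not self.region_ids:
            return True
        seen = {self.region_ids[0]}
        stack = [self.region_ids[0]]
        while stack:
            r = stack.pop()
            for s in self.neighbors.get(r, frozenset()):
                if s not in seen:
                    seen.add(s)
                    stack.append(s)
        return len(seen) == self.n_regions


def read_region_graph(path) -> RegionGraph:
    """Read a plain-text adjacency file (BayesX ``.gra`` dialect).

    Format: first line is the number of regions R; then for each region three
    lines — its label, its neighbor count N_s, and a whitespace-separated line
    of 0-based neighbor indices (empty when N_s = 0).
    """
    text = _read_text(path)
    tokens_by_line = [ln.strip() for ln in text.splitlines()]
    lines = [ln for ln in tokens_by_line if ln != "" or True]  # keep empties: a
    # region with no neighbors legitimately has an empty index line.
    it = iter(lines)
    try:
        first = next(it)
        nr = int(first)
    except (StopIteration, ValueError) as e:
        raise ValueError("graph file: first line must be the region count") from e
    labels: list[str] = []
    raw_nb: list[list[int]] = []
    for _ in range(nr):
        try:
            label = next(it)
            ns = int(next(it))
            idx_line = next(it)
        except StopIteration as e:
            raise ValueError("graph file: truncated") from e
        idx = [int(t) for t in idx_line.split()]
        if len(idx) != ns:
            raise ValueError(
                f"region {label!r}: declares {ns} neighbors but lists {len(idx)}"
            )
        labels.append(label)
        raw_nb.append(idx)
    neighbors = {}
    for i, label in enumerate(labels):
        for j in raw_nb[i]:
            if not 0 <= j < nr:
                raise ValueError(f"region {label!r}: neighbor index {j} out of range")
        neighbors[label] = frozenset(labels[j] for j in raw_nb[i])
    return RegionGraph(tuple(labels), neighbors)  # symmetry checked in ctor


def write_region_graph(graph: RegionGraph, path) -> None:
    pos = {r: i for i, r in enumerate(graph.region_ids)}
    out = [str(graph.n_regions)]
    for r in graph.region_ids:
        nb = sorted(graph.neighbors.get(r, frozenset()), key=pos.__getitem__)
        out.append(r)
        out.append(str(len(nb)))
        out.append(" ".join(str(pos[s]) for s in nb))
    _write_text(path, "\n".join(out) + "\n")


def geojson_to_region_graph(path) -> RegionGraph:
    """Queen-contiguity adjacency from a GeoJSON FeatureCollection of polygons.

    Features need a ``region_id`` (or ``name``) property. Two regions are
    neighbours when their polygons touch or overlap (shared boundary point
    suffices — queen contiguity).
    """
    from shapely.geometry import shape

    obj = json.loads(_read_text(path))
    feats = obj.get("features", [])
    ids, geoms = [], []
    for f in feats:
        props = f.get("properties", {})
        rid = props.get("region_id", props.get("name"))
        if rid is None:
            raise ValueError("GeoJSON feature lacks a region_id/name property")
        ids.append(str(rid))
        geoms.append(shape(f["geometry"]))
    edges = []
    for i in range(len(ids)):
        for j in range(i + 1, len(ids)):
            if geoms[i].touches(geoms[j]) or geoms[i].intersects(geoms[j]):
                edges.append((ids[i], ids[j]))
    return RegionGraph.from_edges(ids, edges)


# ---------------------------------------------------------------------------
# Child records / dataset
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ChildRecord:
    """One child's outcome, age, location and covariate levels."""

    outcome: int
    age_months: int
    region_id: str
    cluster_id: str
    covariates: Mapping[str, str]


@dataclass
class Dataset:
    """Validated child-level table plus cluster coordinates and schema.

    ``records`` holds columns ``outcome, age_months, region_id, cluster_id``
    followed by one column per schema covariate; ``cluster_coords`` is indexed
    by cluster_id with columns ``lon, lat``.
    """

    records: pd.DataFrame
    cluster_coords: pd.DataFrame
    schema: CovariateSchema = field(default_factory=default_schema)

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        df = self.records
        n = len(df)
        if n < 1:
            raise ValueError("dataset must contain at least one record")
        required = ["outcome", "age_months", "region_id", "cluster_id"]
        for col in required:
            if col not in df.columns:
                raise ValueError(f"missing required column {col!r}")
        bad = ~df["outcome"].isin(OUTCOME_CATEGORIES)
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"row {row}: outcome {df['outcome'].iloc[row]!r} not in "
                f"{OUTCOME_CATEGORIES}"
            )
        if (df["age_months"] < 0).any() or (df["age_months"] > 59).any():
            raise ValueError("age_months must lie in 0-59")
        for cov in self.schema:
            if cov.name not in df.columns:
                raise ValueError(f"missing covariate column {cov.name!r}")
            bad = ~df[cov.name].isin(cov.levels)
            if bad.any():
                row = int(np.flatnonzero(bad.to_numpy())[0])
                raise ValueError(
                    f"row {row}: covariate {cov.name!r} has unknown level "
                    f"{df[cov.name].iloc[row]!r} (levels: {cov.levels})"
                )
        # every cluster has coordinates, and maps to exactly one region
        known = set(self.cluster_coords.index)
        missing = set(df["cluster_id"]) - known
        if missing:
            raise ValueError(f"records reference unknown clusters: {sorted(missing)[:5]}")
        if not np.all(np.isfinite(self.cluster_coords[["lon", "lat"]].to_numpy())):
            raise ValueError("non-finite cluster coordinates")
        per_cluster = df.groupby("cluster_id", sort=False)["region_id"].nunique()
        multi = per_cluster[per_cluster > 1]
        if len(multi):
            raise ValueError(
                f"clusters mapped to more than one region: {list(multi.index)[:5]}"
            )

    @property
    def n(self) -> int:
        return len(self.records)

    def category_counts(self) -> np.ndarray:
        """Counts over the four outcome categories, in order 0..3."""
        c = self.records["outcome"].value_counts()
        return np.array([int(c.get(l, 0)) for l in OUTCOME_CATEGORIES])

    def validate_against(self, graph: RegionGraph) -> None:
        unknown = set(self.records["region_id"]) - set(graph.region_ids)
        if unknown:
            raise ValueError(f"records reference regions not in graph: {sorted(unknown)}")

    def iter_records(self) -> Iterator[ChildRecord]:
        cov_names = self.schema.names
        for row in self.records.itertuples(index=False):
            d = row._asdict()
            yield ChildRecord(
                outcome=int(d["outcome"]),
                age_months=int(d["age_months"]),
                region_id=str(d["region_id"]),
                cluster_id=str(d["cluster_id"]),
                covariates={k: d[k] for k in cov_names},
            )


def read_dataset(path, schema: CovariateSchema | None = None,
                 graph: RegionGraph | None = None) -> Dataset:
    """Read a child-level CSV into a validated :class:`Dataset`.

    Expected header: ``outcome, age_months, region_id, cluster_id, lon, lat``
    then one column per schema covariate. Rows with a missing outcome or
    missing region are dropped (count logged); an unknown covariate level or
    an unknown region (when ``graph`` is given) is a hard error.
    """
    schema = schema or default_schema()
    df = pd.read_csv(_open_read(path))
    required = ["outcome", "age_months", "region_id", "cluster_id", "lon", "lat"]
    missing_cols = [c for c in required + list(schema.names) if c not in df.columns]
    if missing_cols:
        raise ValueError(f"CSV header missing columns: {missing_cols}")
    drop = df["outcome"].isna() | df["region_id"].isna()
    if drop.any():
        logger.info("dropping %d rows with missing outcome/region", int(drop.sum()))
        df = df.loc[~drop].reset_index(drop=True)
    df["outcome"] = df["outcome"].astype(int)
    df["age_months"] = df["age_months"].astype(int)
    df["region_id"] = df["region_id"].astype(str)
    df["cluster_id"] = df["cluster_id"].astype(str)
    coords = (df.groupby("cluster_id", sort=False)[["lon", "lat"]]
                .agg(["first", "nunique"]))
    if (coords[("lon", "nunique")] > 1).any() or (coords[("lat", "nunique")] > 1).any():
        raise ValueError("a cluster appears with conflicting coordinates")
    cluster_coords = pd.DataFrame({
        "lon": coords[("lon", "first")],
        "lat": coords[("lat", "first")],
    })
    cluster_coords.index.name = "cluster_id"
    records = df[["outcome", "age_months", "region_id", "cluster_id"]
                 + list(schema.names)].copy()
    ds = Dataset(records=records, cluster_coords=cluster_coords, schema=schema)
    if graph is not None:
        ds.validate_against(graph)
    return ds


def write_dataset(dataset: Dataset, path) -> None:
    """Write the dataset back to the canonical CSV layout (UTF-8)."""
    df = dataset.records.copy()
    df.insert(4, "lon", dataset.cluster_coords["lon"].reindex(df["cluster_id"]).to_numpy())
    df.insert(5, "lat", dataset.cluster_coords["lat"].reindex(df["cluster_id"]).to_numpy())
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    _write_text(path, buf.getvalue())


# ---------------------------------------------------------------------------
# small I/O helpers ("-" means stdin/stdout)
# ---------------------------------------------------------------------------

def _open_read(path):
    if str(path) == "-":
        return sys.stdin
    return Path(path).open("r", encoding="utf-8")


def _read_text(path) -> str:
    if str(path) == "-":
        return sys.stdin.read()
    return Path(path).read_text(encoding="utf-8")


def _write_text(path, text: str) -> None:
    if str(path) == "-":
        sys.stdout.write(text)
    else:
        Path(path).write_text(text, encoding="utf-8")
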