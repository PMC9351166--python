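"""Domain containers and geospatial plumbing.

Everything downstream works with four containers: :class:`AreaTable`
(polygon units of analysis with population and covariates),
:class:`PointEvents` (projected event points with a year label),
:class:`SpatialWeights` (sparse contiguity / nearest-neighbour structure)
and :class:`CountPanel` (area x year event counts).

Coordinates are assumed projected planar metres throughout; input that
looks like lon/lat degrees is refused because kernel bandwidths and
centroid distances are metric.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import shapely
from scipy import sparse
from scipy.spatial.distance import cdist
from shapely.geometry import mapping, shape
from shapely.strtree import STRtree

logger = logging.getLogger("urbanscan")

__all__ = [
    "ConfigurationError",
    "DataError",
    "AreaTable",
    "PointEvents",
    "SpatialWeights",
    "CountPanel",
    "read_areas",
    "write_areas",
    "read_events",
    "write_events",
    "build_weights",
    "aggregate_events",
    "centroid_distances",
]


class ConfigurationError(ValueError):
    """A parameter or config field is missing or out of range."""


class DataError(ValueError):
    """Input data violate a structural requirement."""


def _check_projected(x: np.ndarray, y: np.ndarray) -> None:
    """Refuse coordinates that look like geographic degrees."""
    if len(x) and np.all(np.abs(x) <= 360.0) and np.all(np.abs(y) <= 90.0):
        raise DataError(
            "coordinates look like lon/lat degrees; projected planar metres "
            "are required (distances and bandwidths are metric)"
        )


@dataclass
class AreaTable:
    """Polygon areal units with population at risk and covariates.

    ``covariates`` is a DataFrame indexed like ``area_id`` holding every
    numeric per-area attribute that is not the id or population field.
    """

    area_id: np.ndarray
    geometry: list
    population: np.ndarray
    covariates: pd.DataFrame

    def __post_init__(self) -> None:
        self.area_id = np.asarray(self.area_id, dtype=object)
        self.population = np.asarray(self.population, dtype=float)
        if len(set(self.area_id)) != len(self.area_id):
            raise DataError("area_id values are not unique")
        if len(self.geometry) != len(self.area_id):
            raise DataError("geometry length does not match area_id")
        for aid, geom in zip(self.area_id, self.geometry):
            if geom is None or geom.is_empty:
                raise DataError(f"area {aid!r}: empty geometry")
            if not geom.is_valid:
                raise DataError(f"area {aid!r}: invalid geometry (self-intersection?)")
        if np.any(self.population < 0):
            raise DataError("negative population")
        cents = np.array([[g.centroid.x, g.centroid.y] for g in self.geometry])
        _check_projected(cents[:, 0], cents[:, 1])
        self._centroids = cents

    @property
    def n(self) -> int:
        return len(self.area_id)

    @property
    def centroids(self) -> np.ndarray:
        """(n, 2) array of polygon centroids, metres."""
        return self._centroids

    def subset(self, mask: np.ndarray) -> "AreaTable":
        idx = np.flatnonzero(mask) if mask.dtype == bool else np.asarray(mask)
        return AreaTable(
            area_id=self.area_id[idx],
            geometry=[self.geometry[i] for i in idx],
            population=self.population[idx],
            covariates=self.covariates.iloc[idx].copy(),
        )


@dataclass
class PointEvents:
    """Projected event points with an integer year and optional category."""

    x: np.ndarray
    y: np.ndarray
    year: np.ndarray
    category: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.year = np.asarray(self.year, dtype=int)
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise DataError("non-finite event coordinates")
        if len(self.x):
            _check_projected(self.x, self.y)

    @property
    def n(self) -> int:
        return len(self.x)

    @property
    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class SpatialWeights:
    """Sparse spatial weights: per-area neighbour lists with positive weights.

    No self-neighbours. For contiguity schemes the adjacency *pattern* is
    symmetric; after row standardization each non-isolated row sums to 1.
    """

    neighbours: list
    weights: list
    row_standardized: bool = False

    def __post_init__(self) -> None:
        for i, (nb, w) in enumerate(zip(self.neighbours, self.weights)):
            nb = np.asarray(nb, dtype=int)
            w = np.asarray(w, dtype=float)
            if i in nb:
                raise DataError(f"row {i}: self-neighbour")
            if len(nb) != len(w) or np.any(w <= 0):
                raise DataError(f"row {i}: weights misaligned or non-positive")
            self.neighbours[i] = nb
            self.weights[i] = w

    @property
    def n(self) -> int:
        return len(self.neighbours)

    @property
    def islands(self) -> list[int]:
        return [i for i, nb in enumerate(self.neighbours) if len(nb) == 0]

    def to_sparse(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for i, (nb, w) in enumerate(zip(self.neighbours, self.weights)):
            rows.extend([i] * len(nb))
            cols.extend(nb.tolist())
            vals.extend(w.tolist())
        return sparse.csr_matrix(
            (vals, (rows, cols)), shape=(self.n, self.n), dtype=float
        )

    def lag(self, x: np.ndarray) -> np.ndarray:
        """Spatial lag Wx."""
        return self.to_sparse() @ np.asarray(x, dtype=float)

    @property
    def s0(self) -> float:
        return float(sum(w.sum() for w in self.weights))

    def standardized(self) -> "SpatialWeights":
        """Return a row-standardized copy (isolated rows stay empty)."""
        new_w = [w / w.sum() if len(w) else w.copy() for w in self.weights]
        return SpatialWeights(
            neighbours=[nb.copy() for nb in self.neighbours],
            weights=new_w,
            row_standardized=True,
        )


@dataclass
class CountPanel:
    """Area x year integer event counts with the population at risk."""

    counts: np.ndarray
    population: np.ndarray
    years: np.ndarray
    unassigned: int = 0
    area_id: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.counts = np.asarray(self.counts, dtype=int)
        self.population = np.asarray(self.population, dtype=float)
        self.years = np.asarray(self.years, dtype=int)
        if self.counts.ndim != 2:
            raise DataError("counts must be 2-D (areas x years)")
        if np.any(self.counts < 0):
            raise DataError("negative counts")
        if self.counts.shape != (len(self.population), len(self.years)):
            raise DataError("counts shape inconsistent with population/years")

    @property
    def n_areas(self) -> int:
        return self.counts.shape[0]

    @property
    def n_years(self) -> int:
        return self.counts.shape[1]

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def area_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def year_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------

def read_areas(path, id_field: str, pop_field: str) -> AreaTable:
    """Read a GeoJSON FeatureCollection of polygons into an :class:`AreaTable`.

    All numeric properties other than the id and population fields become
    covariate columns.
    """
    with open(path) as fh:
        gj = json.load(fh)
    feats = gj.get("features")
    if feats is None:
        raise ConfigurationError(f"{path}: not a GeoJSON FeatureCollection")
    ids, geoms, pops, rows = [], [], [], []
    for k, feat in enumerate(feats):
        props = feat.get("properties", {})
        if id_field not in props:
            raise ConfigurationError(f"feature {k}: missing id field {id_field!r}")
        if pop_field not in props:
            raise ConfigurationError(f"feature {k}: missing population field {pop_field!r}")
        aid = props[id_field]
        geom = shape(feat["geometry"]) if feat.get("geometry") else None
        if geom is None or geom.is_empty:
            raise DataError(f"area {aid!r}: empty or missing geometry")
        if geom.geom_type not in ("Polygon", "MultiPolygon"):
            raise DataError(f"area {aid!r}: geometry is {geom.geom_type}, not polygonal")
        ids.append(aid)
        geoms.append(geom)
        pops.append(props[pop_field])
        rows.append(
            {
                key: val
                for key, val in props.items()
                if key not in (id_field, pop_field)
                and isinstance(val, (int, float))
                and not isinstance(val, bool)
            }
        )
    cov = pd.DataFrame(rows)
    cov.index = pd.Index(ids, name="area_id")
    return AreaTable(
        area_id=np.array(ids, dtype=object),
        geometry=geoms,
        population=np.array(pops, dtype=float),
        covariates=cov,
    )


def write_areas(areas: AreaTable, path, id_field="area_id", pop_field="population") -> None:
    """Write an AreaTable back to GeoJSON (round-trips ids, population, covariates)."""
    feats = []
    for i in range(areas.n):
        props = {id_field: areas.area_id[i], pop_field: areas.population[i]}
        props.update(areas.covariates.iloc[i].to_dict())
        feats.append(
            {
                "type": "Feature",
                "geometry": mapping(areas.geometry[i]),
                "properties": props,
            }
        )
    with open(path, "w") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_events(path, year_field: str = "year", study_period=None) -> PointEvents:
    """Read events from a CSV (x, y, year columns) or GeoJSON points file.

    Rows with years outside ``study_period`` (inclusive pair) are dropped
    with a logged count.
    """
    path = str(path)
    if path.endswith((".geojson", ".json")):
        with open(path) as fh:
            gj = json.load(fh)
        xs, ys, yrs, cats = [], [], [], []
        for feat in gj.get("features", []):
            geom = feat.get("geometry") or {}
            if geom.get("type") != "Point":
                raise DataError("event GeoJSON must contain Point features")
            xs.append(geom["coordinates"][0])
            ys.append(geom["coordinates"][1])
            yrs.append(feat.get("properties", {}).get(year_field))
            cats.append(feat.get("properties", {}).get("category"))
        df = pd.DataFrame({"x": xs, "y": ys, year_field: yrs, "category": cats})
    else:
        df = pd.read_csv(path)
        for col in ("x", "y", year_field):
            if col not in df.columns:
                raise ConfigurationError(f"{path}: missing column {col!r}")
    for col in ("x", "y"):
        bad = pd.to_numeric(df[col], errors="coerce").isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise DataError(f"{path}: non-numeric coordinate in row {row}")
    df = df.dropna(subset=["x", "y", year_field])
    year = pd.to_numeric(df[year_field]).astype(int).to_numpy()
    if study_period is not None:
        lo, hi = study_period
        keep = (year >= lo) & (year <= hi)
        dropped = int((~keep).sum())
        if dropped:
            logger.info("read_events: dropped %d events outside study period %s", dropped, study_period)
        df, year = df[keep], year[keep]
    cat = df["category"].to_numpy() if "category" in df.columns else None
    return PointEvents(
        x=df["x"].to_numpy(float), y=df["y"].to_numpy(float), year=year, category=cat
    )


def write_events(events: PointEvents, path) -> None:
    df = pd.DataFrame({"x": events.x, "y": events.y, "year": events.year})
    if events.category is not None:
        df["category"] = events.category
    df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# Weights, aggregation, distances
# ---------------------------------------------------------------------------

def build_weights(
    areas: AreaTable,
    scheme: str = "queen",
    row_standardize: bool = True,
    k: int = 4,
) -> SpatialWeights:
    """Build contiguity (queen/rook) or k-nearest-centroid weights.

    Queen: any shared boundary point (edge or vertex). Rook: shared edge of
    positive length. Binary weights, optionally row-standardized. Isolated
    areas are kept but logged; if every area is isolated the weights are
    useless for autocorrelation and an error is raised.
    """
    n = areas.n
    if n < 2:
        raise ConfigurationError("need at least 2 areas to build weights")
    neighbours: list[np.ndarray]
    if scheme in ("queen", "rook"):
        tree = STRtree(areas.geometry)
        neighbours = []
        for i, geom in enumerate(areas.geometry):
            cand = tree.query(geom)
            nb = []
            for j in cand:
                j = int(j)
                if j == i:
                    continue
                inter = geom.intersection(areas.geometry[j])
                if inter.is_empty:
                    continue
                if scheme == "queen" or inter.length > 0:
                    nb.append(j)
            neighbours.append(np.array(sorted(nb), dtype=int))
    elif scheme == "knn":
        D = centroid_distances(areas)
        np.fill_diagonal(D, np.inf)
        order = np.argsort(D, axis=1, kind="stable")[:, :k]
        neighbours = [np.sort(order[i]) for i in range(n)]
    else:
        raise ConfigurationError(f"unknown weights scheme {scheme!r}")
    islands = [i for i, nb in enumerate(neighbours) if len(nb) == 0]
    if len(islands) == n:
        raise DataError("all areas are isolated; spatial autocorrelation undefined")
    if islands:
        logger.warning("build_weights: %d isolated areas: %s", len(islands), islands)
    w = SpatialWeights(
        neighbours=neighbours,
        weights=[np.ones(len(nb)) for nb in neighbours],
        row_standardized=False,
    )
    return w.standardized() if row_standardize else w


def aggregate_events(events: PointEvents, areas: AreaTable, years) -> CountPanel:
    """Aggregate point events to an area x year count panel.

    Boundary points are assigned to exactly one area: the first containing
    (covering) polygon in stable input order. Events outside all polygons
    are tallied in ``unassigned`` rather than silently dropped.
    """
    years = np.asarray(list(years), dtype=int)
    year_pos = {int(y): t for t, y in enumerate(years)}
    counts = np.zeros((areas.n, len(years)), dtype=int)
    unassigned = 0
    tree = STRtree(areas.geometry)
    pts = shapely.points(events.x, events.y)
    hit_rows, hit_pts = tree.query(pts, predicate="intersects")
    # group candidate containing areas per point; assign first in area order
    assigned = {}
    for pt_i, ar_i in zip(hit_rows, hit_pts):
        pt_i, ar_i = int(pt_i), int(ar_i)
        if pt_i not in assigned or ar_i < assigned[pt_i]:
            assigned[pt_i] = ar_i
    for e in range(events.n):
        t = year_pos.get(int(events.year[e]))
        if t is None:
            continue
        if e in assigned:
            counts[assigned[e], t] += 1
        else:
            unassigned += 1
    if unassigned:
        logger.warning("aggregate_events: %d events outside all polygons", unassigned)
    return CountPanel(
        counts=counts,
        population=areas.population.copy(),
        years=years,
        unassigned=unassigned,
        area_id=areas.area_id.copy(),
    )


def centroid_distances(areas: AreaTable) -> np.ndarray:
    """Symmetric Euclidean centroid distance matrix (metres), zero diagonal."""
    if areas.n < 2:
        raise ConfigurationError("need at least 2 areas")
    D = cdist(areas.centroids, areas.centroids)
    np.fill_diagonal(D, 0.0)
    return D
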