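"""Spatial weight matrices over areal units.

Two constructions are supported, matching standard disease-mapping
practice: Queen contiguity (areas are neighbours if their polygons share
any boundary point or vertex) and a distance band (areas are neighbours if
their centroids lie within a fixed planar distance). Weights are binary
(0/1), unstandardised, with no self-neighbours; the intrinsic CAR prior in
the model normalises through the neighbour-count divisor, so no row
standardisation is ever applied here.

Coordinates are planar, in kilometres (projected); geometry IO goes
through GeoJSON, neighbour lists through the GeoDa GAL exchange format.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.sparse.csgraph import connected_components
from shapely.geometry import Polygon, shape


@dataclass
class AreaGeometry:
    area_id: str
    polygon: Polygon
    centroid: tuple[float, float] | None = None

    def __post_init__(self):
        if self.centroid is None:
            c = self.polygon.centroid
            self.centroid = (c.x, c.y)
        if not all(np.isfinite(self.centroid)):
            raise ValueError(f"area {self.area_id!r}: non-finite centroid")


@dataclass
class NeighbourSummary:
    mean: float
    median: float
    min: int
    max: int
    sd: float

    def as_dict(self) -> dict:
        return {
            "mean": self.mean,
            "median": self.median,
            "min": self.min,
            "max": self.max,
            "sd": self.sd,
        }


@dataclass
class WeightMatrix:
    """Symmetric binary neighbour structure over ``n`` areas.

    ``neighbours[j]`` is a sorted integer array of the neighbours of area
    j; ``weights[j]`` the aligned positive weights (all 1.0 for both
    constructors). ``ids`` maps index -> area_id.
    """

    ids: list
    neighbours: list
    weights: list
    kind: str  # "queen" | "distance_band" | "custom"
    band_km: float | None = None
    _index: dict = field(default_factory=dict, repr=False)

    def __post_init__(self):
        if len(set(self.ids)) != len(self.ids):
            raise ValueError("duplicate area ids")
        self._index = {a: i for i, a in enumerate(self.ids)}
        self.neighbours = [np.asarray(nb, dtype=int) for nb in self.neighbours]
        self.weights = [np.asarray(w, dtype=float) for w in self.weights]
        self.validate()

    @property
    def n(self) -> int:
        return len(self.ids)

    def index_of(self, area_id) -> int:
        return self._index[area_id]

    def validate(self):
        nbr_sets = [set(nb.tolist()) for nb in self.neighbours]
        for j, nbrs in enumerate(nbr_sets):
            if j in nbrs:
                raise ValueError(f"area {self.ids[j]!r} listed as its own neighbour")
            if (self.weights[j] <= 0).any():
                raise ValueError("weights must be strictly positive")
            for k in nbrs:
                if j not in nbr_sets[k]:
                    raise ValueError(
                        f"asymmetric neighbour structure: {self.ids[j]!r} -> "
                        f"{self.ids[k]!r} but not back (CAR requires symmetry)"
                    )

    def neighbour_counts(self) -> np.ndarray:
        return np.array([len(nb) for nb in self.neighbours], dtype=int)

    def to_sparse(self) -> sparse.csr_matrix:
        rows, cols, vals = [], [], []
        for j, (nb, w) in enumerate(zip(self.neighbours, self.weights)):
            rows.extend([j] * len(nb))
            cols.extend(nb.tolist())
            vals.extend(w.tolist())
        return sparse.csr_matrix((vals, (rows, cols)), shape=(self.n, self.n))

    def components(self):
        """(number of connected components, per-area component labels)."""
        if self.n == 0:
            return 0, np.array([], dtype=int)
        ncomp, labels = connected_components(self.to_sparse(), directed=False)
        return int(ncomp), labels

    def isolated(self) -> list:
        return [self.ids[j] for j in np.flatnonzero(self.neighbour_counts() == 0)]


def _check_areas(areas):
    ids = [a.area_id for a in areas]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate area ids in geometry")
    return ids


def queen_contiguity(areas, snap_tol: float = 1e-9) -> WeightMatrix:
    """Queen contiguity: neighbours share at least one boundary vertex.

    Vertices are snapped to a grid of spacing ``snap_tol`` before
    comparison, so exact toy lattices and slightly inexact real
    coordinates both work.
    """
    if len(areas) < 2:
        raise ValueError("queen contiguity needs at least 2 areas")
    ids = _check_areas(areas)
    vertex_owner: dict[tuple, set] = {}
    for j, a in enumerate(areas):
        coords = np.asarray(a.polygon.exterior.coords)
        snapped = {tuple(np.round(xy / snap_tol).astype(np.int64)) for xy in coords}
        if len(snapped) < 3:
            raise ValueError(
                f"area {a.area_id!r}: degenerate polygon (<3 distinct vertices)"
            )
        for v in snapped:
            vertex_owner.setdefault(v, set()).add(j)
    nbrs = [set() for _ in areas]
    for owners in vertex_owner.values():
        for j in owners:
            nbrs[j] |= owners - {j}
    neighbours = [np.array(sorted(s), dtype=int) for s in nbrs]
    return WeightMatrix(
        ids=ids,
        neighbours=neighbours,
        weights=[np.ones(len(nb)) for nb in neighbours],
        kind="queen",
    )


def _centroids(areas) -> np.ndarray:
    xy = np.array([a.centroid for a in areas], dtype=float)
    if not np.isfinite(xy).all():
        raise ValueError("non-finite centroid")
    return xy


def distance_band(areas, band_km: float) -> WeightMatrix:
    """Distance-band weights: w_jk = 1 iff 0 < d(centroid_j, centroid_k) <= band.

    Isolated areas are permitted (the model fitter rejects them unless
    overridden) but trigger a warning.
    """
    if band_km <= 0:
        raise ValueError("band_km must be positive")
    ids = _check_areas(areas)
    xy = _centroids(areas)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    adj = (d > 0) & (d <= band_km)
    np.fill_diagonal(adj, False)
    neighbours = [np.flatnonzero(adj[j]) for j in range(len(areas))]
    W = WeightMatrix(
        ids=ids,
        neighbours=neighbours,
        weights=[np.ones(len(nb)) for nb in neighbours],
        kind="distance_band",
        band_km=float(band_km),
    )
    if W.isolated():
        warnings.warn(
            f"distance band {band_km} km leaves isolated areas: {W.isolated()}",
            stacklevel=2,
        )
    return W


def min_connecting_band(areas) -> float:
    """Smallest distance band leaving no area isolated.

    Equals max_j min_{k != j} d(j, k): any band >= this value gives every
    area at least one neighbour; any smaller band isolates at least one.
    """
    if len(areas) < 2:
        raise ValueError("need at least 2 areas")
    xy = _centroids(areas)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(-1))
    np.fill_diagonal(d, np.inf)
    return float(d.min(axis=1).max())


def neighbour_summary(W: WeightMatrix) -> NeighbourSummary:
    """Summary statistics of the per-area neighbour counts (sample sd)."""
    c = W.neighbour_counts()
    return NeighbourSummary(
        mean=float(c.mean()),
        median=float(np.median(c)),
        min=int(c.min()),
        max=int(c.max()),
        sd=float(c.std(ddof=1)) if len(c) > 1 else 0.0,
    )


# ---------------------------------------------------------------------------
# IO: GAL neighbour lists, GeoJSON geometry, centroid CSV


def write_gal(W: WeightMatrix, path):
    with open(path, "w", encoding="utf-8") as fh:
        fh.write(f"0 {W.n} areas area_id\n")
        for j, aid in enumerate(W.ids):
            nb = W.neighbours[j]
            fh.write(f"{aid} {len(nb)}\n")
            fh.write(" ".join(str(W.ids[k]) for k in nb) + "\n")


def read_gal(path, kind: str = "custom", band_km: float | None = None) -> WeightMatrix:
    """Read a GeoDa GAL neighbour-list file.

    Accepts both the bare "n" header and the GeoDa "0 n <name> <field>"
    header. Asymmetric files are rejected: the CAR prior needs a symmetric
    structure.
    """
    with open(path, encoding="utf-8") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty GAL file")
    header = lines[0].split()
    try:
        n = int(header[1]) if len(header) >= 2 else int(header[0])
    except ValueError as e:
        raise ValueError(f"{path}:1: cannot parse GAL header {lines[0]!r}") from e
    ids, raw = [], {}
    i = 1
    for _ in range(n):
        if i >= len(lines):
            raise ValueError(f"{path}:{i + 1}: truncated GAL file")
        head = lines[i].split()
        if len(head) != 2:
            raise ValueError(f"{path}:{i + 1}: expected 'id count', got {lines[i]!r}")
        aid, k = head[0], int(head[1])
        if k > 0:
            if i + 1 >= len(lines):
                raise ValueError(f"{path}:{i + 2}: truncated GAL file")
            nbr_ids = lines[i + 1].split()
            if len(nbr_ids) != k:
                raise ValueError(
                    f"{path}:{i + 2}: area {aid!r} declares {k} neighbours, "
                    f"found {len(nbr_ids)}"
                )
        else:
            nbr_ids = []
        ids.append(aid)
        raw[aid] = nbr_ids
        i += 2 if k > 0 else 1
    index = {a: j for j, a in enumerate(ids)}
    neighbours = []
    for aid in ids:
        try:
            neighbours.append(np.array(sorted(index[b] for b in raw[aid]), dtype=int))
        except KeyError as e:
            raise ValueError(f"{path}: area {aid!r} references unknown id {e}") from e
    return WeightMatrix(
        ids=ids,
        neighbours=neighbours,
        weights=[np.ones(len(nb)) for nb in neighbours],
        kind=kind,
        band_km=band_km,
    )


def read_geojson(path, id_property: str = "area_id") -> list:
    """Read polygon areas from a GeoJSON FeatureCollection."""
    with open(path, encoding="utf-8") as fh:
        gj = json.load(fh)
    areas = []
    for feat in gj["features"]:
        geom = shape(feat["geometry"])
        if geom.geom_type == "MultiPolygon":
            geom = max(geom.geoms, key=lambda g: g.area)
        if geom.geom_type != "Polygon":
            raise ValueError(f"unsupported geometry type {geom.geom_type}")
        areas.append(AreaGeometry(area_id=str(feat["properties"][id_property]), polygon=geom))
    return areas


def write_geojson(areas, path, id_property: str = "area_id", extra_properties=None):
    feats = []
    for a in areas:
        props = {id_property: a.area_id}
        if extra_properties is not None:
            props.update(extra_properties.get(a.area_id, {}))
        feats.append(
            {
                "type": "Feature",
                "properties": props,
                "geometry": {
                    "type": "Polygon",
                    "coordinates": [list(map(list, a.polygon.exterior.coords))],
                },
            }
        )
    with open(path, "w", encoding="utf-8") as fh:
        json.dump({"type": "FeatureCollection", "features": feats}, fh)


def read_centroids(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    for col in ("area_id", "x_km", "y_km"):
        if col not in df.columns:
            raise ValueError(f"{path}: centroid CSV lacks column {col!r}")
    return df
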