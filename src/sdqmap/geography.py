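"""Synthetic ward geographies and queen-contiguity adjacency.

The study region is abstracted as a tessellation of the unit square into
``n_wards`` polygons. Two layouts are supported:

* ``grid`` — near-square grid of rectangular cells; queen adjacency
  (sharing an edge or a corner point) is derived from grid coordinates.
* ``voronoi`` — random Voronoi tessellation; seed points are reflected
  across the square's edges so every cell is finite and the cells tile the
  square exactly. Adjacency is derived from the Voronoi ridge structure
  (two wards are neighbours iff their cells share a ridge), which for
  points in general position coincides with queen contiguity.

Real ward boundaries can be supplied as GeoJSON instead; queen adjacency is
then recomputed geometrically with shapely.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import Voronoi
from shapely.geometry import MultiPolygon, Polygon, box, mapping, shape


@dataclass
class GeographyConfig:
    n_wards: int = 21
    layout: str = "voronoi"  # "voronoi" or "grid"
    population_weights: np.ndarray | None = None  # simplex over wards
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_wards < 2:
            raise ValueError(f"n_wards must be >= 2, got {self.n_wards}")
        if self.layout not in ("voronoi", "grid"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.population_weights is not None:
            w = np.asarray(self.population_weights, dtype=float)
            if w.shape != (self.n_wards,) or np.any(w < 0):
                raise ValueError("population_weights must be a non-negative "
                                 f"vector of length {self.n_wards}")
            if not np.isclose(w.sum(), 1.0):
                raise ValueError("population_weights must sum to 1")
            self.population_weights = w


@dataclass
class Geography:
    """Ward set with polygons and a binary queen-adjacency matrix."""

    ward_ids: list[int]
    polygons: list[Polygon]
    adjacency: np.ndarray  # (n, n) binary symmetric, zero diagonal

    @property
    def n_wards(self) -> int:
        return len(self.ward_ids)

    def to_geojson(self) -> dict:
        feats = [
            {
                "type": "Feature",
                "properties": {"ward_id": int(wid)},
                "geometry": mapping(poly),
            }
            for wid, poly in zip(self.ward_ids, self.polygons)
        ]
        return {"type": "FeatureCollection", "features": feats}

    def write_geojson(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_geojson(), indent=1))

    def write_adjacency_csv(self, path: str | Path) -> None:
        df = pd.DataFrame(self.adjacency.astype(int),
                          index=self.ward_ids, columns=self.ward_ids)
        df.to_csv(path)


def validate_adjacency(W: np.ndarray) -> None:
    """Check symmetry, zero diagonal and connectivity of a weight matrix."""
    W = np.asarray(W)
    if W.ndim != 2 or W.shape[0] != W.shape[1]:
        raise ValueError("adjacency must be square")
    if not np.array_equal(W, W.T):
        raise ValueError("adjacency must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("adjacency diagonal must be zero")
    if np.any(W.sum(axis=1) == 0):
        raise ValueError("every ward must have at least one neighbour")
    # breadth-first search for connectivity
    n = W.shape[0]
    seen = np.zeros(n, dtype=bool)
    stack = [0]
    seen[0] = True
    while stack:
        i = stack.pop()
        for j in np.nonzero(W[i] > 0)[0]:
            if not seen[j]:
                seen[j] = True
                stack.append(int(j))
    if not seen.all():
        raise ValueError("adjacency graph is not connected")


def _grid_dims(n: int) -> tuple[int, int]:
    """Rows x cols for the most square grid with rows*cols >= n."""
    rows = int(np.floor(np.sqrt(n)))
    while n % rows != 0 and rows > 1:
        rows -= 1
    if rows == 1 and n > 3:  # prime n: use an uneven last row instead
        rows = int(np.floor(np.sqrt(n)))
    cols = int(np.ceil(n / rows))
    return rows, cols


def _generate_grid(cfg: GeographyConfig) -> Geography:
    rows, cols = _grid_dims(cfg.n_wards)
    coords = [(r, c) for r in range(rows) for c in range(cols)][: cfg.n_wards]
    dx, dy = 1.0 / cols, 1.0 / rows
    polys = [box(c * dx, r * dy, (c + 1) * dx, (r + 1) * dy) for r, c in coords]
    n = cfg.n_wards
    W = np.zeros((n, n), dtype=int)
    for i, (ri, ci) in enumerate(coords):
        for j, (rj, cj) in enumerate(coords):
            if i != j and abs(ri - rj) <= 1 and abs(ci - cj) <= 1:
                W[i, j] = 1
    return Geography(list(range(n)), polys, W)


def _generate_voronoi(cfg: GeographyConfig) -> Geography:
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_wards
    # Lloyd-style relaxation keeps cells reasonably even
    pts = rng.uniform(0.05, 0.95, size=(n, 2))
    square = box(0.0, 0.0, 1.0, 1.0)
    for _ in range(3):
        polys, _ = _voronoi_cells(pts, square)
        pts = np.array([np.asarray(p.centroid.coords[0]) for p in polys])
    polys, W = _voronoi_cells(pts, square)
    return Geography(list(range(n)), polys, W)


def _voronoi_cells(pts: np.ndarray, square: Polygon):
    """Finite Voronoi cells of ``pts`` in the unit square via reflection.

    Reflecting the generators across all four edges makes every original
    cell bounded; ridges between two original generators give adjacency.
    """
    n = len(pts)
    refl = [pts]
    for axis, bound in ((0, 0.0), (0, 1.0), (1, 0.0), (1, 1.0)):
        m = pts.copy()
        m[:, axis] = 2 * bound - m[:, axis]
        refl.append(m)
    vor = Voronoi(np.vstack(refl))
    polys = []
    for i in range(n):
        region = vor.regions[vor.point_region[i]]
        poly = Polygon(vor.vertices[region]).intersection(square)
        if isinstance(poly, MultiPolygon):  # numerical slivers
            poly = max(poly.geoms, key=lambda g: g.area)
        polys.append(poly)
    W = np.zeros((n, n), dtype=int)
    for (a, b) in vor.ridge_points:
        if a < n and b < n:
            W[a, b] = W[b, a] = 1
    return polys, W


def generate_geography(cfg: GeographyConfig) -> Geography:
    """Generate ward polygons tiling the unit square plus queen adjacency."""
    geo = _generate_grid(cfg) if cfg.layout == "grid" else _generate_voronoi(cfg)
    validate_adjacency(geo.adjacency)
    return geo


def queen_adjacency_from_polygons(polygons: list[Polygon]) -> np.ndarray:
    """Binary queen-contiguity matrix: wards sharing any border segment or
    point are neighbours."""
    n = len(polygons)
    W = np.zeros((n, n), dtype=int)
    for i in range(n):
        for j in range(i + 1, n):
            inter = polygons[i].intersection(polygons[j])
            if not inter.is_empty and inter.area == 0.0:
                W[i, j] = W[j, i] = 1
    return W


def read_geojson(path: str | Path) -> Geography:
    """Load a ward FeatureCollection (``ward_id`` property per feature) and
    derive queen adjacency geometrically."""
    gj = json.loads(Path(path).read_text())
    ward_ids, polys = [], []
    for feat in gj["features"]:
        ward_ids.append(int(feat["properties"]["ward_id"]))
        polys.append(shape(feat["geometry"]))
    order = np.argsort(ward_ids)
    ward_ids = [ward_ids[i] for i in order]
    polys = [polys[i] for i in order]
    W = queen_adjacency_from_polygons(polys)
    return Geography(ward_ids, polys, W)


def read_adjacency_csv(path: str | Path) -> np.ndarray:
    df = pd.read_csv(path, index_col=0)
    W = df.to_numpy()
    validate_adjacency(W)
    return W
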