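"""Star-convex polygons: representation, area, IoU, and rasterization.

Coordinate convention (shared by every module): positions are ``(row, col)``,
0-based, with pixel centers at integer coordinates. Ray angles are measured
from the +column axis, with the +row axis (image "down") at ``pi/2``; ray ``k``
of ``n`` points at ``theta_k = 2*pi*k/n``.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np
import shapely
from matplotlib.path import Path as MplPath
from shapely.geometry import Polygon as ShapelyPolygon

__all__ = [
    "StarPolygon",
    "ray_directions",
    "polygon_vertices",
    "polygon_area",
    "polygon_iou",
    "rasterize_polygon",
    "polygons_to_csv",
    "polygons_from_csv",
    "polygon_to_geojson",
]


@dataclass
class StarPolygon:
    """A star-convex polygon: a center plus radial distances along fixed rays.

    Vertex ``k`` lies at ``center + distances[k] * ray_directions(n_rays)[k]``;
    connecting the vertices in ray order yields a simple polygon that is
    star-shaped about the center. ``score`` is the detection confidence
    attached to the polygon when it is used as a segmentation proposal.
    """

    center: tuple[float, float]
    distances: np.ndarray
    score: float = 1.0

    def __post_init__(self) -> None:
        self.distances = np.asarray(self.distances, dtype=np.float64)
        if self.distances.ndim != 1 or self.distances.size < 3:
            raise ValueError("distances must be a 1-D sequence of length >= 3")
        if np.any(self.distances < 0):
            raise ValueError("radial distances must be non-negative")
        if not 0.0 <= self.score <= 1.0:
            raise ValueError(f"score must be in [0, 1], got {self.score}")
        self.center = (float(self.center[0]), float(self.center[1]))

    @property
    def n_rays(self) -> int:
        return int(self.distances.size)

    def vertices(self) -> np.ndarray:
        return polygon_vertices(self)

    def area(self) -> float:
        return polygon_area(self)


@lru_cache(maxsize=32)
def _ray_directions_cached(n_rays: int) -> np.ndarray:
    theta = 2.0 * np.pi * np.arange(n_rays) / n_rays
    dirs = np.stack([np.sin(theta), np.cos(theta)], axis=1)  # (row, col)
    dirs.setflags(write=False)
    return dirs


def ray_directions(n_rays: int) -> np.ndarray:
    """Unit vectors of the ``n_rays`` equiangular radial directions.

    Returns an ``(n_rays, 2)`` array of ``(row, col)`` unit vectors; direction
    ``k`` has angle ``2*pi*k/n_rays`` from the +column axis.
    """
    if n_rays < 3:
        raise ValueError(f"n_rays must be >= 3, got {n_rays}")
    return _ray_directions_cached(int(n_rays))


def polygon_vertices(p: StarPolygon) -> np.ndarray:
    """Ordered ``(n_rays, 2)`` array of the polygon's ``(row, col)`` vertices."""
    dirs = ray_directions(p.n_rays)
    return np.asarray(p.center, dtype=np.float64) + p.distances[:, None] * dirs


def polygon_area(p: StarPolygon) -> float:
    """Shoelace area of the vertex polygon (non-negative)."""
    v = polygon_vertices(p)
    r, c = v[:, 0], v[:, 1]
    return float(0.5 * abs(np.dot(c, np.roll(r, -1)) - np.dot(r, np.roll(c, -1))))


def to_shapely(p: StarPolygon) -> ShapelyPolygon:
    """The polygon as a shapely geometry ((x, y) = (col, row))."""
    v = polygon_vertices(p)
    return ShapelyPolygon(np.column_stack([v[:, 1], v[:, 0]]))


def polygon_iou(a: StarPolygon, b: StarPolygon) -> float:
    """Area intersection-over-union of two star polygons.

    Exact polygon clipping via shapely; the IoU of two degenerate (zero-area)
    polygons is defined as 0.
    """
    ga, gb = to_shapely(a), to_shapely(b)
    if not ga.is_valid:
        ga = ga.buffer(0)
    if not gb.is_valid:
        gb = gb.buffer(0)
    area_a, area_b = ga.area, gb.area
    if area_a == 0.0 or area_b == 0.0:
        return 0.0
    inter = ga.intersection(gb).area
    union = area_a + area_b - inter
    if union <= 0.0:
        return 0.0
    return float(min(1.0, inter / union))


def rasterize_polygon(p: StarPolygon, shape: tuple[int, int]) -> np.ndarray:
    """Boolean mask of pixels whose centers lie inside the polygon.

    Pixel ``(i, j)`` is set iff the point ``(i, j)`` is inside the vertex
    polygon under the even-odd rule; pixels outside ``shape`` are dropped.
    """
    h, w = int(shape[0]), int(shape[1])
    if h <= 0 or w <= 0:
        raise ValueError(f"shape must be positive, got {shape}")
    mask = np.zeros((h, w), dtype=bool)
    if polygon_area(p) == 0.0:
        return mask
    v = polygon_vertices(p)
    r0 = max(0, int(np.floor(v[:, 0].min())))
    r1 = min(h - 1, int(np.ceil(v[:, 0].max())))
    c0 = max(0, int(np.floor(v[:, 1].min())))
    c1 = min(w - 1, int(np.ceil(v[:, 1].max())))
    if r0 > r1 or c0 > c1:
        return mask
    rr, cc = np.mgrid[r0 : r1 + 1, c0 : c1 + 1]
    pts = np.column_stack([rr.ravel(), cc.ravel()])
    path = MplPath(v, closed=False)
    inside = path.contains_points(pts)
    mask[r0 : r1 + 1, c0 : c1 + 1] = inside.reshape(rr.shape)
    return mask


def polygons_to_csv(polygons: Sequence[StarPolygon], path) -> None:
    """Write polygons as CSV rows: center_row, center_col, score, d_0..d_{n-1}."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh)
        for p in polygons:
            writer.writerow(
                [f"{p.center[0]:.4f}", f"{p.center[1]:.4f}", f"{p.score:.6f}"]
                + [f"{d:.4f}" for d in p.distances]
            )


def polygons_from_csv(path) -> list[StarPolygon]:
    polygons = []
    with open(path, newline="") as fh:
        for row in csv.reader(fh):
            if not row:
                continue
            vals = [float(x) for x in row]
            polygons.append(StarPolygon((vals[0], vals[1]), np.array(vals[3:]), score=vals[2]))
    return polygons


def polygon_to_geojson(p: StarPolygon) -> dict:
    """GeoJSON-style dict with an (x, y) = (col, row) exterior ring."""
    v = polygon_vertices(p)
    ring = [[float(c), float(r)] for r, c in v]
    ring.append(ring[0])
    return {
        "type": "Feature",
        "geometry": {"type": "Polygon", "coordinates": [ring]},
        "properties": {"score": float(p.score), "center": [p.center[0], p.center[1]]},
    }
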