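"""2D alpha-shapes of planar point sets.

The alpha-shape used throughout this package is the Delaunay filtration
variant: a triangle of the Delaunay triangulation belongs to the shape at
scale ``alpha`` iff its circumradius is <= ``alpha`` (boundary inclusive, so
the optimum alpha always coincides with a spectrum value).  Edges and
vertices are carried implicitly as faces of kept triangles.  Two kept
triangles belong to the same region iff they share a full edge.

Coordinates are (row, col) pixel centres, 0-based, with the row axis
increasing downward; all lengths are in pixels and areas in squared pixels.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import Delaunay as _QhullDelaunay

from .errors import DegenerateInputError

logger = logging.getLogger(__name__)

__all__ = [
    "PointSet",
    "DelaunayTriangulation",
    "AlphaShape",
    "circumradius",
    "triangulate",
    "build_alpha_shape",
    "count_regions",
    "covers_all_points",
    "alpha_spectrum",
]

_COLLINEAR_TOL = 1e-12


@dataclass(frozen=True)
class PointSet:
    """A deduplicated planar point set.

    Parameters
    ----------
    points : (n, 2) float array
        Unique, finite (row, col) coordinates.
    """

    points: np.ndarray

    @property
    def n(self) -> int:
        return len(self.points)

    @classmethod
    def from_array(cls, arr) -> "PointSet":
        """Validate, deduplicate (lexicographic order) and wrap coordinates."""
        pts = np.asarray(arr, dtype=float)
        if pts.ndim != 2 or pts.shape[1] != 2:
            raise DegenerateInputError(
                f"expected an (n, 2) coordinate array, got shape {pts.shape}"
            )
        if not np.all(np.isfinite(pts)):
            raise DegenerateInputError("point coordinates must be finite")
        unique = np.unique(pts, axis=0)
        if len(unique) < len(pts):
            logger.info(
                "deduplicated %d duplicate point(s)", len(pts) - len(unique)
            )
        return cls(points=unique)


@dataclass(frozen=True)
class DelaunayTriangulation:
    """Delaunay triangulation with per-triangle circumradii.

    ``neighbors[t, k]`` is the index of the triangle sharing the edge of
    triangle ``t`` opposite its ``k``-th vertex, or -1 on the hull boundary.
    """

    points: np.ndarray        # (n, 2)
    simplices: np.ndarray     # (m, 3) vertex indices
    neighbors: np.ndarray     # (m, 3) triangle indices, -1 = none
    circumradii: np.ndarray   # (m,)
    areas: np.ndarray         # (m,) triangle areas

    @property
    def n_points(self) -> int:
        return len(self.points)

    @property
    def n_triangles(self) -> int:
        return len(self.simplices)


@dataclass(frozen=True)
class AlphaShape:
    """The alpha-shape of a triangulation at a fixed scale.

    ``kept`` indexes into ``source.simplices``; ``region_labels`` assigns an
    edge-connected component id to every kept triangle.
    """

    source: DelaunayTriangulation
    alpha: float
    kept: np.ndarray            # indices of kept triangles, sorted
    region_labels: np.ndarray   # (len(kept),) component ids
    n_regions: int
    area: float
    covered_points: np.ndarray  # sorted vertex indices covered by kept triangles

    @property
    def n_kept(self) -> int:
        return len(self.kept)


def circumradius(p1, p2, p3) -> float:
    """Radius of the unique circle through three non-collinear points.

    Uses R = abc / (4A) with A the triangle area.
    """
    p1 = np.asarray(p1, dtype=float)
    p2 = np.asarray(p2, dtype=float)
    p3 = np.asarray(p3, dtype=float)
    a = np.linalg.norm(p2 - p3)
    b = np.linalg.norm(p1 - p3)
    c = np.linalg.norm(p1 - p2)
    cross = (p2[0] - p1[0]) * (p3[1] - p1[1]) - (p2[1] - p1[1]) * (p3[0] - p1[0])
    area = 0.5 * abs(cross)
    if area <= _COLLINEAR_TOL * max(a, b, c) ** 2:
        raise DegenerateInputError(
            "circumradius of a (near-)collinear triple is undefined"
        )
    return float(a * b * c / (4.0 * area))


def _triangle_geometry(points: np.ndarray, simplices: np.ndarray):
    """Vectorised circumradii and areas for all simplices."""
    p1 = points[simplices[:, 0]]
    p2 = points[simplices[:, 1]]
    p3 = points[simplices[:, 2]]
    a = np.linalg.norm(p2 - p3, axis=1)
    b = np.linalg.norm(p1 - p3, axis=1)
    c = np.linalg.norm(p1 - p2, axis=1)
    cross = (p2[:, 0] - p1[:, 0]) * (p3[:, 1] - p1[:, 1]) - (
        p2[:, 1] - p1[:, 1]
    ) * (p3[:, 0] - p1[:, 0])
    areas = 0.5 * np.abs(cross)
    with np.errstate(divide="ignore", invalid="ignore"):
        radii = a * b * c / (4.0 * areas)
    return radii, areas


def triangulate(points) -> DelaunayTriangulation:
    """Delaunay-triangulate a planar point set.

    Accepts a :class:`PointSet` or any (n, 2) array-like; duplicates are
    removed first.  Raises :class:`DegenerateInputError` for fewer than 3
    distinct points or an all-collinear configuration.
    """
    ps = points if isinstance(points, PointSet) else PointSet.from_array(points)
    pts = ps.points
    if ps.n < 3:
        raise DegenerateInputError(
            f"need at least 3 distinct points to triangulate, got {ps.n}"
        )
    centred = pts - pts.mean(axis=0)
    if np.linalg.matrix_rank(centred, tol=1e-9 * max(1.0, np.abs(pts).max())) < 2:
        raise DegenerateInputError("all points are collinear")
    qh = _QhullDelaunay(pts)
    radii, areas = _triangle_geometry(pts, qh.simplices)
    # Qhull never emits zero-area 2D simplices for valid input, but near-
    # degenerate slivers can occur on integer grids; drop exact zeros.
    good = areas > 0
    if not np.all(good):
        logger.warning("dropped %d zero-area sliver triangle(s)", int((~good).sum()))
        keep_map = -np.ones(len(qh.simplices), dtype=int)
        keep_map[good] = np.arange(int(good.sum()))
        simplices = qh.simplices[good]
        neighbors = qh.neighbors[good]
        neighbors = np.where(neighbors >= 0, keep_map[neighbors], -1)
        radii, areas = radii[good], areas[good]
    else:
        simplices = qh.simplices
        neighbors = qh.neighbors
    return DelaunayTriangulation(
        points=pts,
        simplices=np.ascontiguousarray(simplices),
        neighbors=np.ascontiguousarray(neighbors),
        circumradii=radii,
        areas=areas,
    )


def _regions(tri: DelaunayTriangulation, kept: np.ndarray):
    """Edge-connected components of the kept triangles."""
    k = len(kept)
    if k == 0:
        return 0, np.empty(0, dtype=int)
    pos = -np.ones(tri.n_triangles, dtype=int)
    pos[kept] = np.arange(k)
    nb = tri.neighbors[kept]                  # (k, 3)
    valid = nb >= 0
    nb_pos = np.where(valid, pos[np.where(valid, nb, 0)], -1)
    rows = np.repeat(np.arange(k), 3)
    cols = nb_pos.ravel()
    ok = cols >= 0
    graph = coo_matrix(
        (np.ones(ok.sum(), dtype=np.int8), (rows[ok], cols[ok])), shape=(k, k)
    )
    n_comp, labels = connected_components(graph, directed=False)
    return int(n_comp), labels


def build_alpha_shape(tri: DelaunayTriangulation, alpha: float) -> AlphaShape:
    """Filter a triangulation at scale ``alpha`` (circumradius <= alpha)."""
    if alpha < 0:
        raise ValueError(f"alpha must be non-negative, got {alpha}")
    kept = np.flatnonzero(tri.circumradii <= alpha)
    n_regions, labels = _regions(tri, kept)
    area = float(tri.areas[kept].sum())
    covered = np.unique(tri.simplices[kept])
    return AlphaShape(
        source=tri,
        alpha=float(alpha),
        kept=kept,
        region_labels=labels,
        n_regions=n_regions,
        area=area,
        covered_points=covered,
    )


def count_regions(shape: AlphaShape) -> int:
    """Number of edge-connected components of kept triangles (0 if empty)."""
    return shape.n_regions


def covers_all_points(shape: AlphaShape) -> bool:
    """True iff every triangulation vertex lies in at least one kept triangle."""
    return len(shape.covered_points) == shape.source.n_points


def alpha_spectrum(tri: DelaunayTriangulation) -> np.ndarray:
    """Strictly increasing distinct circumradii; the shape is constant on the
    half-open intervals between consecutive values."""
    return np.unique(tri.circumradii)
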