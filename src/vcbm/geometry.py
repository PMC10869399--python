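"""Delaunay neighbourhoods, tumour-boundary identification and boundary distances.

Cells are represented only by their centre points; cell shapes are the Voronoi
regions dual to the Delaunay triangulation, but no Voronoi areas are ever
computed — all dynamics use the Delaunay adjacency alone.  Voronoi regions of
hull points are unbounded, which is irrelevant here for the same reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import ConvexHull, Delaunay, QhullError, cKDTree
from scipy.spatial.distance import cdist

HEALTHY = 0
TUMOUR = 1

#: magnitude (mm) of the deterministic per-index jitter applied before
#: triangulating, to break cocircular ties reproducibly across platforms
_JITTER_MM = 1e-9
_GOLDEN = 0.6180339887498949  # frac(1/phi), used for index-seeded jitter angles


class GeometryError(ValueError):
    """Degenerate input geometry (too few points, collinear set, empty tumour)."""


@dataclass
class PointConfiguration:
    """Cell centre points with their kinds.

    Parameters
    ----------
    points : (n, 2) float array
        Cell centre coordinates in mm.
    kinds : (n,) int array
        ``TUMOUR`` (1) or ``HEALTHY`` (0) per point.
    """

    points: np.ndarray
    kinds: np.ndarray

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float)
        self.kinds = np.asarray(self.kinds, dtype=np.int8)
        if self.points.ndim != 2 or self.points.shape[1] != 2:
            raise GeometryError("points must be an (n, 2) array")
        if not np.all(np.isfinite(self.points)):
            raise GeometryError("all coordinates must be finite")
        if self.kinds.shape != (len(self.points),):
            raise GeometryError("kinds must parallel points")
        if not np.all((self.kinds == HEALTHY) | (self.kinds == TUMOUR)):
            raise GeometryError("kinds must be HEALTHY (0) or TUMOUR (1)")


@dataclass
class Adjacency:
    """Symmetric, irreflexive neighbour relation over point indices.

    Stored as a sorted edge list plus a CSR neighbour table for O(1) access
    to the neighbourhood N(i).
    """

    n: int
    edges: np.ndarray  # (m, 2) int, each row sorted, rows lexicographically sorted
    indptr: np.ndarray = field(repr=False)
    indices: np.ndarray = field(repr=False)

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i]:self.indptr[i + 1]]

    def degree(self) -> np.ndarray:
        return np.diff(self.indptr)

    def edge_set(self) -> set[tuple[int, int]]:
        return {(int(a), int(b)) for a, b in self.edges}


def _csr_from_edges(n: int, edges: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    if len(edges) == 0:
        return np.zeros(n + 1, dtype=np.int64), np.empty(0, dtype=np.int64)
    src = np.concatenate([edges[:, 0], edges[:, 1]])
    dst = np.concatenate([edges[:, 1], edges[:, 0]])
    order = np.lexsort((dst, src))
    src, dst = src[order], dst[order]
    indptr = np.zeros(n + 1, dtype=np.int64)
    np.add.at(indptr, src + 1, 1)
    np.cumsum(indptr, out=indptr)
    return indptr, dst


_jitter_cache: dict[str, np.ndarray] = {"table": np.empty((0, 2))}


def _index_jitter(n: int) -> np.ndarray:
    """Deterministic O(1e-9 mm) offsets seeded from the point index.

    Uses a golden-ratio angle sequence so every index gets a distinct,
    platform-independent direction; breaks exact cocircularity (e.g. on
    hexagonal lattices) without perturbing the stored positions.  The table
    is cached and grown on demand (it depends only on the index).
    """
    table = _jitter_cache["table"]
    if len(table) < n:
        k = np.arange(max(n, 2 * len(table)))
        ang = 2.0 * np.pi * ((k * _GOLDEN) % 1.0)
        table = _JITTER_MM * np.column_stack([np.cos(ang), np.sin(ang)])
        _jitter_cache["table"] = table
    return table[:n]


def _delaunay_adjacency(
    pts: np.ndarray, max_edge_factor: float | None, rest_length: float
) -> Adjacency:
    """Hot-path core of :func:`build_adjacency` (no validation)."""
    n = len(pts)
    try:
        tri = Delaunay(pts + _index_jitter(n))
    except QhullError as exc:
        raise GeometryError(f"degenerate geometry (collinear points?): {exc}") from exc

    s = tri.simplices.astype(np.int64)
    raw = np.concatenate([s[:, [0, 1]], s[:, [1, 2]], s[:, [0, 2]]])
    lo = raw.min(axis=1)
    hi = raw.max(axis=1)
    keys = np.unique(lo * n + hi)  # dedupe via scalar keys: much faster than axis=0
    edges = np.column_stack([keys // n, keys % n])

    if max_edge_factor is not None:
        diff = pts[edges[:, 0]] - pts[edges[:, 1]]
        lengths = np.sqrt(diff[:, 0] ** 2 + diff[:, 1] ** 2)
        edges = edges[lengths <= max_edge_factor * rest_length]

    indptr, indices = _csr_from_edges(n, edges)
    return Adjacency(n=n, edges=edges, indptr=indptr, indices=indices)


def build_adjacency(
    config: PointConfiguration,
    max_edge_factor: float | None = 1.5,
    rest_length: float = 1.0,
) -> Adjacency:
    """Delaunay edge set with long spurious hull edges pruned.

    Edges longer than ``max_edge_factor * rest_length`` are removed: Delaunay
    triangulation of a finite domain creates long-range hull edges with no
    biological meaning.  Pass ``max_edge_factor=None`` to keep all edges.

    Raises
    ------
    GeometryError
        If fewer than 3 points are supplied or all points are collinear.
    """
    pts = config.points
    n = len(pts)
    if n < 3:
        raise GeometryError(f"triangulation requires >= 3 points, got {n}")
    # collinearity must be detected before the tie-breaking jitter hides it
    rel = pts - pts[0]
    v = rel[np.argmax(np.einsum("ij,ij->i", rel, rel))]
    area = np.abs(rel[:, 0] * v[1] - rel[:, 1] * v[0])
    scale = max(float(np.abs(rel).max()), 1.0)
    if np.all(area <= 1e-12 * scale * scale):
        raise GeometryError("degenerate geometry: all points are collinear")
    return _delaunay_adjacency(pts, max_edge_factor, rest_length)


def find_boundary(config: PointConfiguration, adj: Adjacency) -> np.ndarray:
    """Indices of tumour cells on the tumour periphery (proliferating edge).

    A tumour cell is on the boundary when it has at least one healthy Delaunay
    neighbour.  If no tumour cell has a healthy neighbour (an all-tumour
    configuration, e.g. mid burn-in), the tumour cells on the convex hull are
    returned so that the periphery stays defined.

    Raises
    ------
    GeometryError
        If the configuration contains no tumour cells.
    """
    kinds = config.kinds
    tumour_idx = np.flatnonzero(kinds == TUMOUR)
    if len(tumour_idx) == 0:
        raise GeometryError("configuration contains no tumour cells")

    if len(adj.edges) > 0:
        e = adj.edges
        ka, kb = kinds[e[:, 0]], kinds[e[:, 1]]
        mixed_a = e[(ka == TUMOUR) & (kb == HEALTHY), 0]
        mixed_b = e[(kb == TUMOUR) & (ka == HEALTHY), 1]
        boundary = np.unique(np.concatenate([mixed_a, mixed_b]))
        if len(boundary) > 0:
            return boundary

    # all-tumour fallback: periphery = tumour points on the convex hull
    tpts = config.points[tumour_idx]
    if len(tumour_idx) == 1:
        return tumour_idx
    if len(tumour_idx) == 2:
        return tumour_idx
    try:
        hull = ConvexHull(tpts)
        return np.sort(tumour_idx[hull.vertices])
    except QhullError:
        return tumour_idx  # collinear tumour set: everything is peripheral


def boundary_distances(
    config: PointConfiguration, boundary: np.ndarray, query: np.ndarray | None = None
) -> np.ndarray:
    """Euclidean distance from each query point to the nearest boundary centre.

    ``query`` is an index array (defaults to all points).  Distances are
    centre-to-centre; a point that is itself on the boundary gets 0.
    """
    boundary = np.asarray(boundary)
    if boundary.size == 0:
        raise GeometryError("boundary is empty")
    if query is None:
        query = np.arange(len(config.points))
    bpts = config.points[boundary]
    qpts = config.points[query]
    if len(bpts) * len(qpts) <= 200_000:
        return cdist(qpts, bpts).min(axis=1)
    tree = cKDTree(bpts)
    d, _ = tree.query(qpts)
    return d


def distance_to_boundary(config: PointConfiguration, boundary, i: int) -> float:
    """min over b in boundary of ||r_i - r_b||; 0 when i is on the boundary."""
    boundary = np.asarray(sorted(boundary) if isinstance(boundary, set) else boundary)
    return float(boundary_distances(config, boundary, np.array([i]))[0])
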