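"""Voxel tessellations and the discrete Laplacian.

A :class:`Grid` is a tessellation of 2D or 3D space into voxels, each of
which can hold a small number of cells.  The only geometric information
the mechanics needs is, for every pair of edge-sharing voxels ``(i, j)``,
the measure of the shared interface ``e_ij`` (edge length in 2D, face area
in 3D) and the distance ``d_ij`` between the voxel centres.  The ratio
``e_ij / d_ij`` is the two-point-flux weight of the edge; assembling these
weights into a sparse matrix gives the discrete Laplacian, which on uniform
structured grids reduces to the familiar finite-difference stencils
(5-point in 2D, 7-point in 3D).

Supported tessellations:

* Cartesian 2D / 3D with square / cubic voxels of side ``h``;
* regular hexagonal 2D lattices (pointy-top, centre spacing ``h``);
* unstructured 2D Voronoi tessellations built from user seed points and
  clipped to a bounding box.

Because all edge weights are positive, the assembled operator satisfies a
discrete maximum principle — unlike, say, cotangent FEM weights on poor
triangulations, negative off-diagonal entries cannot arise here.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import scipy.sparse as sp

from .exceptions import AssemblyError, ConfigurationError

__all__ = [
    "Grid",
    "LaplacianOperator",
    "build_structured_grid",
    "build_voronoi_grid",
    "assemble_laplacian",
    "grid_to_dataframe",
]

_SQRT3 = math.sqrt(3.0)


@dataclass
class Grid:
    """Voxel tessellation with edge-based connectivity.

    Parameters
    ----------
    dim : int
        Spatial dimension, 2 or 3.
    h : float
        Characteristic voxel size (centre spacing on structured grids).
    centers : (N, dim) ndarray
        Voxel centre coordinates.
    edges : (M, 2) int ndarray
        Undirected edge list, each row ``(i, j)`` with ``i < j``.
    edge_measure : (M,) ndarray
        Shared edge length (2D) or face area (3D), ``e_ij > 0``.
    center_distance : (M,) ndarray
        Distance between voxel centres, ``d_ij > 0``.
    voxel_measure : (N,) ndarray
        Area (2D) or volume (3D) of each voxel (lumped mass).
    external_boundary : (N,) bool ndarray
        Flags for voxels on the fixed outer domain boundary.
    kind : str
        One of ``cartesian2d``, ``cartesian3d``, ``hexagonal``, ``voronoi``.
    shape : tuple or None
        Lattice extent for structured grids (row-major indexing).
    """

    dim: int
    h: float
    centers: np.ndarray
    edges: np.ndarray
    edge_measure: np.ndarray
    center_distance: np.ndarray
    voxel_measure: np.ndarray
    external_boundary: np.ndarray
    kind: str
    shape: tuple | None = None

    # derived connectivity, built in __post_init__
    _indptr: np.ndarray = field(init=False, repr=False)
    _indices: np.ndarray = field(init=False, repr=False)
    _edge_of: np.ndarray = field(init=False, repr=False)
    _edge_lookup: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.centers = np.asarray(self.centers, dtype=float)
        self.edges = np.asarray(self.edges, dtype=np.int64).reshape(-1, 2)
        self.edge_measure = np.asarray(self.edge_measure, dtype=float)
        self.center_distance = np.asarray(self.center_distance, dtype=float)
        if np.any(self.edge_measure <= 0) or np.any(self.center_distance <= 0):
            raise AssemblyError("edge measures and centre distances must be positive")
        n = self.n_voxels
        # directed adjacency in CSR layout: both orientations of every edge
        src = np.concatenate([self.edges[:, 0], self.edges[:, 1]])
        dst = np.concatenate([self.edges[:, 1], self.edges[:, 0]])
        eid = np.concatenate([np.arange(self.n_edges)] * 2)
        order = np.argsort(src, kind="stable")
        self._indices = dst[order]
        self._edge_of = eid[order]
        self._indptr = np.zeros(n + 1, dtype=np.int64)
        np.add.at(self._indptr, src + 1, 1)
        np.cumsum(self._indptr, out=self._indptr)
        self._edge_lookup = {
            (int(a), int(b)): int(m)
            for m, (a, b) in enumerate(self.edges)
        }

    # -- basic queries ---------------------------------------------------

    @property
    def n_voxels(self) -> int:
        return self.centers.shape[0]

    @property
    def n_edges(self) -> int:
        return self.edges.shape[0]

    @property
    def weights(self) -> np.ndarray:
        """Two-point-flux weight ``e_ij / d_ij`` per undirected edge."""
        return self.edge_measure / self.center_distance

    def neighbours(self, i: int) -> np.ndarray:
        """Voxel indices sharing an edge/face with voxel ``i``."""
        return self._indices[self._indptr[i]:self._indptr[i + 1]]

    def incident_edges(self, i: int) -> np.ndarray:
        """Undirected edge ids incident to voxel ``i`` (parallel to
        :meth:`neighbours`)."""
        return self._edge_of[self._indptr[i]:self._indptr[i + 1]]

    def edge_id(self, i: int, j: int) -> int:
        """Undirected edge index of the neighbour pair ``(i, j)``."""
        key = (i, j) if i < j else (j, i)
        try:
            return self._edge_lookup[key]
        except KeyError:
            raise ValueError(f"voxels {i} and {j} are not neighbours") from None

    def are_neighbours(self, i: int, j: int) -> bool:
        key = (i, j) if i < j else (j, i)
        return key in self._edge_lookup

    def unit_vector(self, i: int, j: int) -> np.ndarray:
        """Unit vector pointing from the centre of voxel ``i`` to ``j``."""
        r = self.centers[j] - self.centers[i]
        return r / np.linalg.norm(r)

    def adjacency(self) -> sp.csr_matrix:
        """Sparse symmetric matrix of edge weights ``e_ij / d_ij``."""
        w = self.weights
        i, j = self.edges[:, 0], self.edges[:, 1]
        return sp.csr_matrix(
            (np.concatenate([w, w]),
             (np.concatenate([i, j]), np.concatenate([j, i]))),
            shape=(self.n_voxels, self.n_voxels),
        )


@dataclass
class LaplacianOperator:
    """Negative-semidefinite discrete Laplacian ``L`` over a grid.

    Off-diagonal entries are the edge weights ``w_ij = e_ij / d_ij`` and the
    diagonal is ``-sum_j w_ij``, so the quasi-steady pressure problem is
    posed as ``-L p = s(u)``.  Row sums vanish (the constant vector lies in
    the kernel) and the matrix is symmetric by construction.
    """

    matrix: sp.csr_matrix
    grid: Grid


def build_structured_grid(kind: str, extent, h: float = 1.0,
                          origin=None) -> Grid:
    """Build a structured voxel grid.

    Parameters
    ----------
    kind : {"cartesian2d", "cartesian3d", "hexagonal"}
        Lattice type.  Hexagonal lattices are 2D, pointy-top, with centre
        spacing ``h`` (edge length ``h/sqrt(3)``, edge-to-centre-distance
        ratio ``1/sqrt(3)``).
    extent : sequence of int
        Voxel counts per axis (2 entries, or 3 for ``cartesian3d``).
    h : float
        Voxel size (centre spacing), ``> 0``.
    origin : sequence of float, optional
        Coordinates of voxel ``(0, 0[, 0])``'s centre; defaults to zero.

    Voxel indexing is row-major over the lattice (the last axis varies
    fastest within a row: ``id = iy * nx + ix`` in 2D), which makes
    snapshots reproducible across runs.
    """
    if h <= 0:
        raise ConfigurationError(f"voxel size h must be positive, got {h}")
    extent = tuple(int(e) for e in np.atleast_1d(extent))
    if any(e < 1 for e in extent):
        raise ConfigurationError(f"extents must be >= 1, got {extent}")

    if kind == "cartesian2d":
        return _cartesian_grid(extent, h, origin, dim=2)
    if kind == "cartesian3d":
        return _cartesian_grid(extent, h, origin, dim=3)
    if kind == "hexagonal":
        return _hexagonal_grid(extent, h, origin)
    raise ConfigurationError(f"unknown grid kind {kind!r}")


def _cartesian_grid(extent, h, origin, dim):
    if len(extent) != dim:
        raise ConfigurationError(
            f"cartesian{dim}d needs {dim} extents, got {extent}")
    shape = tuple(reversed(extent))  # row-major: slowest axis last in id
    nx = extent[0]
    ny = extent[1]
    nz = extent[2] if dim == 3 else 1
    ix, iy, iz = np.meshgrid(np.arange(nx), np.arange(ny),
                             np.arange(nz), indexing="ij")
    # id = iz*(nx*ny) + iy*nx + ix
    ids = iz * (nx * ny) + iy * nx + ix
    centers = np.zeros((nx * ny * nz, dim))
    centers[ids.ravel(), 0] = (ix * h).ravel()
    centers[ids.ravel(), 1] = (iy * h).ravel()
    if dim == 3:
        centers[ids.ravel(), 2] = (iz * h).ravel()
    if origin is not None:
        centers += np.asarray(origin, dtype=float)

    edges = []
    for axis, n_axis in enumerate((nx, ny, nz)[:dim]):
        if n_axis < 2:
            continue
        sl = [slice(None)] * 3
        sl[axis] = slice(None, -1)
        a = ids[tuple(sl)].ravel()
        sl[axis] = slice(1, None)
        b = ids[tuple(sl)].ravel()
        edges.append(np.column_stack([a, b]))
    edges = (np.vstack(edges) if edges
             else np.empty((0, 2), dtype=np.int64))
    edges.sort(axis=1)

    e = h if dim == 2 else h * h
    n_edges = edges.shape[0]
    boundary = np.zeros(nx * ny * nz, dtype=bool)
    on_edge = (ix == 0) | (ix == nx - 1) | (iy == 0) | (iy == ny - 1)
    if dim == 3:
        on_edge |= (iz == 0) | (iz == nz - 1)
    boundary[ids.ravel()] = on_edge.ravel()
    return Grid(
        dim=dim, h=h, centers=centers, edges=edges,
        edge_measure=np.full(n_edges, e),
        center_distance=np.full(n_edges, h),
        voxel_measure=np.full(nx * ny * nz, h ** dim),
        external_boundary=boundary,
        kind=f"cartesian{dim}d", shape=extent,
    )


def _hexagonal_grid(extent, h, origin):
    if len(extent) != 2:
        raise ConfigurationError(f"hexagonal grid needs 2 extents, got {extent}")
    nx, ny = extent
    # pointy-top hexagons, odd-row offset layout; id = row * nx + col
    cols, rows = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    ids = rows * nx + cols
    centers = np.zeros((nx * ny, 2))
    centers[ids.ravel(), 0] = ((cols + 0.5 * (rows % 2)) * h).ravel()
    centers[ids.ravel(), 1] = (rows * (h * _SQRT3 / 2.0)).ravel()
    if origin is not None:
        centers += np.asarray(origin, dtype=float)

    edge_set = []
    for r in range(ny):
        off = (-1, 0) if r % 2 == 0 else (0, 1)
        for c in range(nx):
            i = r * nx + c
            # east neighbour
            if c + 1 < nx:
                edge_set.append((i, i + nx * 0 + 1))
            # two north neighbours
            if r + 1 < ny:
                for dc in off:
                    cc = c + dc
                    if 0 <= cc < nx:
                        edge_set.append((i, (r + 1) * nx + cc))
    edges = np.array(sorted((min(a, b), max(a, b)) for a, b in edge_set),
                     dtype=np.int64).reshape(-1, 2)
    n_edges = edges.shape[0]
    boundary = np.zeros(nx * ny, dtype=bool)
    on_edge = (cols == 0) | (cols == nx - 1) | (rows == 0) | (rows == ny - 1)
    boundary[ids.ravel()] = on_edge.ravel()
    return Grid(
        dim=2, h=h, centers=centers, edges=edges,
        edge_measure=np.full(n_edges, h / _SQRT3),
        center_distance=np.full(n_edges, float(h)),
        voxel_measure=np.full(nx * ny, _SQRT3 / 2.0 * h * h),
        external_boundary=boundary,
        kind="hexagonal", shape=(nx, ny),
    )


def build_voronoi_grid(seed_points, bounding_box) -> Grid:
    """Build an unstructured 2D grid from the Voronoi tessellation of
    ``seed_points``, clipped to ``bounding_box = (xmin, ymin, xmax, ymax)``.

    Voxel centres are the seed points themselves; two voxels are
    neighbours iff their clipped Voronoi cells share an edge of positive
    length (cells meeting only at a point are *not* neighbours).  The edge
    measure is the shared edge's length and the centre distance is the
    distance between the seed points.  Cells touching the bounding box are
    flagged as external boundary.
    """
    import shapely
    from scipy.spatial import Delaunay, QhullError
    from shapely.geometry import MultiPoint, box as shapely_box
    from shapely.ops import voronoi_diagram

    pts = np.asarray(seed_points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2:
        raise ConfigurationError("seed points must be an (n, 2) array")
    if pts.shape[0] < 3:
        raise ConfigurationError("need at least 3 seed points")
    if np.unique(pts, axis=0).shape[0] != pts.shape[0]:
        raise ConfigurationError("duplicate seed points")
    xmin, ymin, xmax, ymax = map(float, bounding_box)
    if not (xmax > xmin and ymax > ymin):
        raise ConfigurationError("degenerate bounding box")
    if (np.any(pts[:, 0] <= xmin) or np.any(pts[:, 0] >= xmax)
            or np.any(pts[:, 1] <= ymin) or np.any(pts[:, 1] >= ymax)):
        raise ConfigurationError("all seed points must lie inside the box")

    try:
        tri = Delaunay(pts)
    except QhullError as err:
        raise ConfigurationError(f"degenerate seed points: {err}") from err

    bbox = shapely_box(xmin, ymin, xmax, ymax)
    diagram = voronoi_diagram(MultiPoint(pts), envelope=bbox)
    cells: list = [None] * len(pts)
    seeds = [shapely.Point(p) for p in pts]
    for poly in diagram.geoms:
        clipped = poly.intersection(bbox)
        for k, s in enumerate(seeds):
            if cells[k] is None and clipped.covers(s):
                cells[k] = clipped
                break
    if any(c is None or c.is_empty for c in cells):
        raise ConfigurationError("Voronoi construction failed to cover all seeds")

    # candidate neighbour pairs = Delaunay edges; keep those whose clipped
    # cells share a boundary segment of positive length
    cand = set()
    for simplex in tri.simplices:
        for a in range(3):
            i, j = int(simplex[a]), int(simplex[(a + 1) % 3])
            cand.add((min(i, j), max(i, j)))
    edges, e_meas, d_meas = [], [], []
    tol = 1e-12 * max(xmax - xmin, ymax - ymin)
    for i, j in sorted(cand):
        shared = cells[i].intersection(cells[j])
        if shared.length > tol:
            edges.append((i, j))
            e_meas.append(shared.length)
            d_meas.append(float(np.linalg.norm(pts[i] - pts[j])))
    if not edges:
        raise ConfigurationError("no positive-length Voronoi edges found")

    boundary = np.array(
        [cell.exterior.intersection(bbox.exterior).length > tol
         for cell in cells], dtype=bool)
    return Grid(
        dim=2, h=float(np.median(d_meas)),
        centers=pts,
        edges=np.array(edges, dtype=np.int64),
        edge_measure=np.array(e_meas),
        center_distance=np.array(d_meas),
        voxel_measure=np.array([c.area for c in cells]),
        external_boundary=boundary,
        kind="voronoi", shape=None,
    )


def assemble_laplacian(grid: Grid) -> LaplacianOperator:
    """Assemble the edge-weighted discrete Laplacian of a grid.

    ``L`` has off-diagonals ``w_ij = e_ij / d_ij`` for every neighbour pair
    and diagonal ``-sum_j w_ij``; on a uniform 2D Cartesian grid with
    ``h = 1`` this is exactly the 5-point stencil.  Pure function: the grid
    is not modified.
    """
    if np.any(grid.edge_measure <= 0):
        raise AssemblyError("grid contains a zero-measure edge")
    w = grid.weights
    i, j = grid.edges[:, 0], grid.edges[:, 1]
    n = grid.n_voxels
    offdiag = sp.coo_matrix(
        (np.concatenate([w, w]),
         (np.concatenate([i, j]), np.concatenate([j, i]))),
        shape=(n, n)).tocsr()
    diag = np.asarray(offdiag.sum(axis=1)).ravel()
    matrix = (offdiag - sp.diags(diag)).tocsr()
    return LaplacianOperator(matrix=matrix, grid=grid)


def grid_to_dataframe(grid: Grid):
    """Tabular (CSV-ready) description of a grid: one row per voxel with
    its centre, neighbour list and per-edge ``e_ij``, ``d_ij`` values."""
    import pandas as pd

    rows = []
    for i in range(grid.n_voxels):
        nbr = grid.neighbours(i)
        eid = grid.incident_edges(i)
        rows.append({
            "voxel": i,
            **{f"x{k}": grid.centers[i, k] for k in range(grid.dim)},
            "neighbours": " ".join(str(int(j)) for j in nbr),
            "e_ij": " ".join(repr(float(grid.edge_measure[m])) for m in eid),
            "d_ij": " ".join(repr(float(grid.center_distance[m])) for m in eid),
            "voxel_measure": grid.voxel_measure[i],
            "external_boundary": bool(grid.external_boundary[i]),
        })
    return pd.DataFrame(rows)
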