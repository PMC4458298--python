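"""Structured triangular meshes for the 2-D diffusion forward model.

The mesher covers an axis-aligned rectangle with a regular grid and splits
every cell into two right triangles.  A structured mesh keeps the forward
model fully reproducible (no external mesh generator) and makes point
location for source placement an O(1) grid lookup.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import InvalidGeometryError


@dataclass(frozen=True)
class Mesh:
    """Triangulation of a rectangle.

    Attributes
    ----------
    nodes : (n, 2) float array
        Node coordinates in mm.
    triangles : (m, 3) int array
        Node index triples, counter-clockwise (positive signed area).
    boundary_edges : (e, 2) int array
        Node index pairs lying on the rectangle perimeter.
    boundary_node_ids : (b,) int array
        Sorted ids of all perimeter nodes.
    grid_shape : (nx, ny)
        Number of grid cells along x and y (structured meshes only).
    extent : (width, height)
        Rectangle dimensions in mm.
    """

    nodes: np.ndarray
    triangles: np.ndarray
    boundary_edges: np.ndarray
    boundary_node_ids: np.ndarray
    grid_shape: tuple = field(default=None)
    extent: tuple = field(default=None)

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    @property
    def n_triangles(self) -> int:
        return self.triangles.shape[0]

    def signed_areas(self) -> np.ndarray:
        p = self.nodes[self.triangles]
        return 0.5 * (
            (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1])
            - (p[:, 2, 0] - p[:, 0, 0]) * (p[:, 1, 1] - p[:, 0, 1])
        )

    def contains_point(self, x: float, y: float) -> bool:
        w, h = self.extent
        return 0.0 <= x <= w and 0.0 <= y <= h


def build_rect_mesh(width: float, height: float, target_edge_len: float) -> Mesh:
    """Triangulate a ``width`` x ``height`` mm rectangle.

    The grid spacing is the largest value <= ``target_edge_len`` that
    divides both sides into an integer number of cells (at least two per
    side, so the mesh resolves the interior).

    Raises
    ------
    InvalidGeometryError
        If any dimension is nonpositive or the requested edge length is
        too coarse for the rectangle.
    """
    if width <= 0 or height <= 0 or target_edge_len <= 0:
        raise InvalidGeometryError(
            f"dimensions must be positive, got {width=} {height=} {target_edge_len=}"
        )
    if target_edge_len > min(width, height) / 2.0:
        raise InvalidGeometryError(
            f"target_edge_len={target_edge_len} too coarse for a "
            f"{width} x {height} rectangle (need at least two cells per side)"
        )
    nx = max(2, int(round(width / target_edge_len)))
    ny = max(2, int(round(height / target_edge_len)))

    xs = np.linspace(0.0, width, nx + 1)
    ys = np.linspace(0.0, height, ny + 1)
    X, Y = np.meshgrid(xs, ys, indexing="xy")
    nodes = np.column_stack([X.ravel(), Y.ravel()])  # id = iy*(nx+1)+ix

    def nid(ix, iy):
        return iy * (nx + 1) + ix

    tris = []
    for iy in range(ny):
        for ix in range(nx):
            a, b = nid(ix, iy), nid(ix + 1, iy)
            c, d = nid(ix + 1, iy + 1), nid(ix, iy + 1)
            tris.append((a, b, c))  # lower-right triangle, CCW
            tris.append((a, c, d))  # upper-left triangle, CCW
    triangles = np.asarray(tris, dtype=np.int64)

    edges = []
    for ix in range(nx):
        edges.append((nid(ix, 0), nid(ix + 1, 0)))
        edges.append((nid(ix, ny), nid(ix + 1, ny)))
    for iy in range(ny):
        edges.append((nid(0, iy), nid(0, iy + 1)))
        edges.append((nid(nx, iy), nid(nx, iy + 1)))
    boundary_edges = np.asarray(edges, dtype=np.int64)
    boundary_node_ids = np.unique(boundary_edges)

    return Mesh(
        nodes=nodes,
        triangles=triangles,
        boundary_edges=boundary_edges,
        boundary_node_ids=boundary_node_ids,
        grid_shape=(nx, ny),
        extent=(width, height),
    )


def locate_point(mesh: Mesh, x: float, y: float):
    """Return (triangle_id, barycentric_weights) of the cell containing (x, y).

    Only valid for structured meshes produced by :func:`build_rect_mesh`.
    """
    if mesh.grid_shape is None:
        raise InvalidGeometryError("point location requires a structured mesh")
    if not mesh.contains_point(x, y):
        raise InvalidGeometryError(f"point ({x}, {y}) outside the mesh extent")
    nx, ny = mesh.grid_shape
    w, h = mesh.extent
    hx, hy = w / nx, h / ny
    ix = min(int(x / hx), nx - 1)
    iy = min(int(y / hy), ny - 1)
    # local coordinates in the cell; diagonal runs bottom-left -> top-right
    u = x / hx - ix
    v = y / hy - iy
    cell = 2 * (iy * nx + ix)
    tri_id = cell if v <= u else cell + 1
    p = mesh.nodes[mesh.triangles[tri_id]]
    T = np.column_stack([p[1] - p[0], p[2] - p[0]])
    lam = np.linalg.solve(T, np.array([x, y]) - p[0])
    bary = np.array([1.0 - lam.sum(), lam[0], lam[1]])
    bary = np.clip(bary, 0.0, 1.0)
    return tri_id, bary / bary.sum()
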