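"""Cross-divided triangulations of square domains.

The domain [0, L]^2 is first split into (L/h)^2 square cells; each cell is
then cross-divided into four triangles through its centroid.  Nodes are the
(L/h + 1)^2 lattice points plus the (L/h)^2 centroids.  Boundary tags follow
the quarter-domain symmetry setup: ``gamma_h`` is the horizontal symmetry
boundary y = 0, ``gamma_v`` the vertical symmetry boundary x = 0, and
``gamma_o`` the outer boundary (x = L or y = L) where far-field Dirichlet
data is imposed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["TriangleMesh", "build_mesh", "mesh_quality", "DegenerateElementError"]


class DegenerateElementError(RuntimeError):
    """An element's Jacobian determinant vanished."""


@dataclass
class TriangleMesh:
    """A P1 triangle mesh that can move with the tissue.

    ``coords`` are the current (deformed) node positions, ``coords0`` the
    reference positions; ``coords = coords0 + u`` with ``u`` the accumulated
    displacement held by the field state.
    """

    coords: np.ndarray  # (n_nodes, 2), current positions
    triangles: np.ndarray  # (n_elems, 3) int
    coords0: np.ndarray = field(default=None)  # type: ignore[assignment]
    gamma_o: np.ndarray = field(default=None)  # type: ignore[assignment]
    gamma_h: np.ndarray = field(default=None)  # type: ignore[assignment]
    gamma_v: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.coords0 is None:
            self.coords0 = self.coords.copy()
        n = self.n_nodes
        for name in ("gamma_o", "gamma_h", "gamma_v"):
            if getattr(self, name) is None:
                setattr(self, name, np.zeros(n, dtype=bool))

    @property
    def n_nodes(self) -> int:
        return self.coords.shape[0]

    @property
    def n_elements(self) -> int:
        return self.triangles.shape[0]

    def signed_jacobians(self) -> np.ndarray:
        """Per-element Jacobian determinants (2x the signed area)."""
        p = self.coords[self.triangles]
        return (p[:, 1, 0] - p[:, 0, 0]) * (p[:, 2, 1] - p[:, 0, 1]) - (
            p[:, 2, 0] - p[:, 0, 0]
        ) * (p[:, 1, 1] - p[:, 0, 1])

    def quality(self) -> float:
        return mesh_quality(self)

    def moved(self, displacement: np.ndarray) -> "TriangleMesh":
        """Copy of the mesh at ``coords0 + displacement``."""
        return TriangleMesh(
            coords=self.coords0 + displacement,
            triangles=self.triangles,
            coords0=self.coords0,
            gamma_o=self.gamma_o,
            gamma_h=self.gamma_h,
            gamma_v=self.gamma_v,
        )


def mesh_quality(mesh: TriangleMesh) -> float:
    """Global mesh-quality ratio min|J| / max|J| over all elements, in (0, 1].

    Rigid motions and uniform scalings leave the ratio unchanged; it
    degrades when deformation becomes spatially uneven.
    """
    jac = np.abs(mesh.signed_jacobians())
    if np.any(jac == 0.0):
        raise DegenerateElementError("element with zero Jacobian determinant")
    return float(jac.min() / jac.max())


def build_mesh(L: float, h: float) -> TriangleMesh:
    """Cross-divided triangulation of [0, L]^2 with cell size ``h``.

    ``L/h`` must be integral.  Produces ``(L/h)^2 * 4`` triangles and
    ``(L/h + 1)^2 + (L/h)^2`` nodes, with boundary masks tagged.
    """
    ratio = L / h
    n = round(ratio)
    if abs(ratio - n) > 1e-9 * max(1.0, ratio) or n < 1:
        raise ValueError(f"L/h must be a positive integer, got {ratio}")
    axis = np.linspace(0.0, L, n + 1)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    lattice = np.column_stack([gx.ravel(), gy.ravel()])
    centers_axis = 0.5 * (axis[:-1] + axis[1:])
    cx, cy = np.meshgrid(centers_axis, centers_axis, indexing="ij")
    centroids = np.column_stack([cx.ravel(), cy.ravel()])
    coords = np.vstack([lattice, centroids])

    def lat(i, j):
        return i * (n + 1) + j

    n_lat = (n + 1) ** 2
    tris = []
    for i in range(n):
        for j in range(n):
            a, b = lat(i, j), lat(i + 1, j)
            c, d = lat(i + 1, j + 1), lat(i, j + 1)
            m = n_lat + i * n + j
            tris += [(a, b, m), (b, c, m), (c, d, m), (d, a, m)]
    triangles = np.array(tris, dtype=np.int64)

    x, y = coords[:, 0], coords[:, 1]
    tol = 1e-12 * max(1.0, L)
    gamma_o = (np.abs(x - L) < tol) | (np.abs(y - L) < tol)
    gamma_h = np.abs(y) < tol
    gamma_v = np.abs(x) < tol
    return TriangleMesh(
        coords=coords,
        triangles=triangles,
        gamma_o=gamma_o,
        gamma_h=gamma_h,
        gamma_v=gamma_v,
    )
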