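"""Vectorized P1 operator assembly with vertex (Newton-Cotes) quadrature.

All integrals use the vertex rule on triangles — exact for linears, and the
rule that makes the consistent mass matrix diagonal (its diagonal equals the
row sums of the exact P1 mass matrix, i.e. classical row-sum lumping).

Operators (``w`` a nodal coefficient field, broadcastable scalar allowed):

``lumped_mass``        m_i           = int phi_i
``stiffness(w)``       K[i, j]       = int w grad phi_j . grad phi_i
``gradient_op(k, w)``  D_k[i, j]     = int w phi_j d_k phi_i

``D_k(w).T`` gives ``int w phi_i d_k phi_j``, the weak nodal derivative used
by the pointwise (ODE-like) equations; nodal derivatives are recovered as
``D_k(1).T @ z / m``.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .mesh import TriangleMesh

__all__ = ["Geometry"]


class Geometry:
    """Element geometry and operator factory for one mesh configuration."""

    def __init__(self, mesh: TriangleMesh):
        self.mesh = mesh
        tri = mesh.triangles
        p = mesh.coords[tri]  # (m, 3, 2)
        d1 = p[:, 1] - p[:, 0]
        d2 = p[:, 2] - p[:, 0]
        det = d1[:, 0] * d2[:, 1] - d2[:, 0] * d1[:, 1]
        self.signed_jac = det
        self.area = 0.5 * np.abs(det)
        # gradients of the three local basis functions, (m, 3, 2)
        b = np.stack(
            [p[:, 1, 1] - p[:, 2, 1], p[:, 2, 1] - p[:, 0, 1], p[:, 0, 1] - p[:, 1, 1]],
            axis=1,
        )
        c = np.stack(
            [p[:, 2, 0] - p[:, 1, 0], p[:, 0, 0] - p[:, 2, 0], p[:, 1, 0] - p[:, 0, 0]],
            axis=1,
        )
        self.grads = np.stack([b, c], axis=2) / det[:, None, None]  # (m, 3, 2)
        self.tri = tri
        n = mesh.n_nodes
        self.n_nodes = n
        # index template for 3x3 local blocks
        self.rows_ab = np.repeat(tri, 3, axis=1).ravel()  # a index, 9 per elem
        self.cols_ab = np.tile(tri, (1, 3)).ravel()  # b index
        self.lumped = np.zeros(n)
        np.add.at(self.lumped, tri.ravel(), np.repeat(self.area / 3.0, 3))

    def _coo(self, values: np.ndarray) -> sparse.csr_matrix:
        n = self.n_nodes
        return sparse.coo_matrix(
            (values.ravel(), (self.rows_ab, self.cols_ab)), shape=(n, n)
        ).tocsr()

    def stiffness(self, w) -> sparse.csr_matrix:
        """int w grad phi_j . grad phi_i with elementwise-averaged coefficient."""
        w_elem = np.mean(np.broadcast_to(np.asarray(w, float), (self.n_nodes,))[self.tri], axis=1)
        # local (a, b): area * wbar * grad_a . grad_b  (symmetric)
        gg = np.einsum("mak,mbk->mab", self.grads, self.grads)
        vals = (self.area * w_elem)[:, None, None] * gg
        return self._coo(vals.transpose(0, 1, 2))

    def gradient_op(self, k: int, w=1.0) -> sparse.csr_matrix:
        """D_k(w)[i, j] = int w phi_j d_k phi_i (vertex quadrature)."""
        w_nodal = np.broadcast_to(np.asarray(w, float), (self.n_nodes,))
        wb = w_nodal[self.tri]  # (m, 3) value at column vertex b
        ga = self.grads[:, :, k]  # (m, 3) d_k phi_a
        vals = (self.area / 3.0)[:, None, None] * ga[:, :, None] * wb[:, None, :]
        return self._coo(vals)

    def nodal_gradient(self, z: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Mass-lumped nodal projection of (d_x z, d_y z) for a P1 field."""
        gx = self.gradient_op(0).T @ z / self.lumped
        gy = self.gradient_op(1).T @ z / self.lumped
        return gx, gy
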