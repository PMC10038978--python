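"""Strain-symmetry dynamics.

The skew part ``omega = eps - eps^T`` of the effective strain obeys a closed
linear system: with ``L12`` the off-diagonal of the spin tensor
``skw(grad v)`` and ``K`` the morphoelastic relaxation coefficient
``zeta [N + eta_II M] c / (1 + a_c_III c)``, the four components of omega
satisfy ``D omega/Dt + B omega = 0`` with a 4x4 matrix ``B`` whose spectrum
has constant real part ``K``.  Symmetry of the strain is therefore an
invariant (initially symmetric stays symmetric), and it is stable iff
``K >= 0``: null-stable for K = 0 (purely imaginary spectrum, perturbations
persist bounded), asymptotically stable for K > 0, unstable for K < 0
(expansion instead of contraction).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np
from scipy.integrate import cumulative_trapezoid

from .kinetics import FieldPoint, strain_relaxation_rate
from .params import ModelParameters

__all__ = [
    "SkewState",
    "skew_part",
    "relaxation_coefficient",
    "skew_relaxation_matrix",
    "classify_symmetry_stability",
    "skew_norm_evolution",
]


@dataclass(frozen=True)
class SkewState:
    """Skew strain components with the coefficients driving their dynamics.

    ``omega`` holds (w11, w12, w21, w22); a skew part derived from a strain
    tensor has w11 = w22 = 0 and w21 = -w12.  ``K`` (1/day) is the
    morphoelastic relaxation coefficient, ``L12`` (1/day) the off-diagonal
    of the spin tensor skw(grad v).
    """

    omega: np.ndarray
    K: float
    L12: float

    @classmethod
    def from_strain(cls, strain: np.ndarray, K: float, L12: float) -> "SkewState":
        return cls(omega=skew_part(strain), K=K, L12=L12)

    def matrix(self) -> np.ndarray:
        return skew_relaxation_matrix(self.K, self.L12)

    def classify(self) -> str:
        return classify_symmetry_stability(self.K)


def skew_part(strain: np.ndarray) -> np.ndarray:
    """omega = eps - eps^T, flattened to (w11, w12, w21, w22)."""
    strain = np.asarray(strain, float)
    omega = strain - strain.T
    return omega.ravel()


def relaxation_coefficient(state: FieldPoint | float, params: ModelParameters | None = None) -> float:
    """The coefficient K, from either a raw value or a model state."""
    if isinstance(state, FieldPoint):
        if params is None:
            raise ValueError("params required to evaluate K from a FieldPoint")
        return float(strain_relaxation_rate(state.N, state.M, state.c, params))
    return float(state)


def skew_relaxation_matrix(K: float, L12: float) -> np.ndarray:
    """The 4x4 matrix B of ``D omega/Dt + B omega = 0`` over
    (w11, w12, w21, w22).

    For K = 0 the matrix is skew-symmetric with spectrum
    {0, 0, +2i L12, -2i L12}; in general every eigenvalue has real part K.
    """
    return np.array(
        [
            [K, -L12, -L12, 0.0],
            [L12, K, 0.0, -L12],
            [L12, 0.0, K, -L12],
            [0.0, L12, L12, K],
        ]
    )


def classify_symmetry_stability(K: float) -> str:
    """``null_stable`` (K = 0), ``a_stable`` (K > 0) or ``unstable`` (K < 0)."""
    if K == 0.0:
        return "null_stable"
    return "a_stable" if K > 0.0 else "unstable"


def skew_norm_evolution(
    K_path: Callable[[float], float] | float,
    omega0: np.ndarray | float,
    t_grid: np.ndarray,
) -> np.ndarray:
    """Frobenius norm ||omega||(t) along a prescribed relaxation history.

    The norm obeys the scalar law ``d||omega||/dt = -K(t) ||omega||`` (the
    spin terms are norm-preserving), so
    ``||omega||(t) = ||omega0|| exp(-int_0^t K)``; the integral is taken with
    the trapezoid rule on ``t_grid``.  A symmetric initial strain
    (omega0 = 0) stays exactly symmetric.
    """
    t_grid = np.asarray(t_grid, float)
    if t_grid.ndim != 1 or np.any(np.diff(t_grid) <= 0):
        raise ValueError("t_grid must be strictly increasing and 1-D")
    omega0 = np.asarray(omega0, float)
    norm0 = float(np.linalg.norm(omega0))
    if callable(K_path):
        K_values = np.array([float(K_path(t)) for t in t_grid])
    else:
        K_values = np.full_like(t_grid, float(K_path))
    integral = cumulative_trapezoid(K_values, t_grid, initial=0.0)
    return norm0 * np.exp(-integral)
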