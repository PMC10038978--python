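"""Pointwise right-hand sides of the contraction model.

These are the non-transport parts of the governing equations: the reaction
kinetics of the four biochemical species, the visco-elastic Cauchy stress,
the myofibroblast traction potential and the morphoelastic strain evolution.
They are shared by the linear-stability machinery and the finite-element
solver, which add the transport/divergence terms in their own discretizations.

All functions accept scalars or numpy arrays (broadcasting over nodes).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .params import ModelParameters

__all__ = [
    "FieldPoint",
    "reaction_terms",
    "cauchy_stress",
    "traction_potential",
    "strain_rhs",
    "strain_relaxation_rate",
]


@dataclass(frozen=True)
class FieldPoint:
    """The nine model unknowns at a single material point."""

    N: float
    M: float
    c: float
    rho: float
    v1: float = 0.0
    v2: float = 0.0
    e11: float = 0.0
    e12: float = 0.0
    e22: float = 0.0

    def strain(self) -> np.ndarray:
        return np.array([[self.e11, self.e12], [self.e12, self.e22]])


def _check_denominators(c, params: ModelParameters) -> None:
    for name, value in (
        ("1 + a_c_III*c", 1.0 + params.a_c_III * np.asarray(c)),
        ("a_c_I + c", params.a_c_I + np.asarray(c)),
        ("a_c_II + c", params.a_c_II + np.asarray(c)),
        ("a_c_IV + c", params.a_c_IV + np.asarray(c)),
    ):
        if np.any(value <= 0.0):
            raise ValueError(f"nonpositive Hill denominator {name}")


def reaction_terms(pt: FieldPoint, params: ModelParameters):
    """Reaction rates (dN/dt, dM/dt, dc/dt, drho/dt) excluding all transport.

    Fibroblasts proliferate logistically with signal-enhanced division and
    differentiate into myofibroblasts at rate ``k_F c``; myofibroblasts only
    proliferate in the presence of signaling molecules.  Signaling molecules
    and collagen are secreted by both cell types and degraded by MMPs, whose
    local-equilibrium concentration gives the ``1/(1 + a_c_III c)`` factor.
    """
    p = params
    N, M, c, rho = pt.N, pt.M, pt.c, pt.rho
    _check_denominators(c, p)
    crowding = 1.0 - p.kappa_F * (N + M)
    mmp = (N + p.eta_II * M) / (1.0 + p.a_c_III * c)
    dN = (
        p.r_F * (1.0 + p.r_F_max * c / (p.a_c_I + c)) * crowding * N ** (1.0 + p.q)
        - p.k_F * c * N
        - p.delta_N * N
    )
    dM = (
        p.r_F * ((1.0 + p.r_F_max) * c / (p.a_c_I + c)) * crowding * M ** (1.0 + p.q)
        + p.k_F * c * N
        - p.delta_M * M
    )
    dc = p.k_c * c / (p.a_c_II + c) * (N + p.eta_I * M) - p.delta_c * mmp * rho * c
    drho = (
        p.k_rho * (1.0 + p.k_rho_max * c / (p.a_c_IV + c)) * (N + p.eta_I * M)
        - p.delta_rho * mmp * rho**2
    )
    return dN, dM, dc, drho


def cauchy_stress(
    sym_grad_v: np.ndarray,
    strain: np.ndarray,
    rho,
    params: ModelParameters,
) -> np.ndarray:
    """Visco-elastic Cauchy stress.

    sigma = mu_1 sym(grad v) + mu_2 tr(sym(grad v)) I
            + E sqrt(rho)/(1+nu) [eps + nu/(1-2 nu) tr(eps) I]

    The stiffness scales with sqrt(collagen density); ``nu`` must stay below
    the incompressible limit 1/2.
    """
    p = params
    if p.nu >= 0.5:
        raise ValueError("nu = 1/2 is the incompressible limit; stress undefined")
    if np.any(np.asarray(rho) < 0):
        raise ValueError("negative collagen density in stress evaluation")
    sym_grad_v = np.asarray(sym_grad_v, dtype=float)
    strain = np.asarray(strain, dtype=float)
    eye = np.eye(2)
    viscous = p.mu_1 * sym_grad_v + p.mu_2 * np.trace(sym_grad_v) * eye
    stiff = p.E * np.sqrt(rho) / (1.0 + p.nu)
    elastic = stiff * (strain + np.trace(strain) * p.nu / (1.0 - 2.0 * p.nu) * eye)
    return viscous + elastic


def traction_potential(M, rho, params: ModelParameters):
    """Isotropic traction potential xi M rho / (R^2 + rho^2).

    The myofibroblast body force is the divergence of this potential times the
    identity; the FEM module applies the divergence weakly.  The potential is
    maximal in rho at rho = R.
    """
    return params.xi * M * rho / (params.R**2 + rho**2)


def strain_relaxation_rate(N, M, c, params: ModelParameters):
    """Morphoelastic relaxation coefficient zeta [N + eta_II M] c / (1 + a_c_III c).

    This is the coefficient K of the strain-symmetry dynamics: positive during
    contraction (c > 0), zero at the healthy equilibrium.
    """
    denom = 1.0 + params.a_c_III * np.asarray(c)
    if np.any(denom <= 0.0):
        raise ValueError("nonpositive MMP-inhibition denominator 1 + a_c_III*c")
    return params.zeta * (N + params.eta_II * M) * np.asarray(c) / denom


def strain_rhs(
    strain: np.ndarray,
    grad_v: np.ndarray,
    N,
    M,
    c,
    params: ModelParameters,
) -> np.ndarray:
    """Material rate of the effective strain, D eps/Dt, solved from the
    morphoelastic evolution law:

    D eps/Dt = -eps skw(grad v) + skw(grad v) eps
               - (tr eps - 1) sym(grad v) - K eps,

    with K the relaxation coefficient of :func:`strain_relaxation_rate`.
    Gradient convention: ``grad_v[k, l] = d v_k / d x_l``.  Symmetric input
    strain yields a symmetric rate.
    """
    strain = np.asarray(strain, dtype=float)
    grad_v = np.asarray(grad_v, dtype=float)
    sym = 0.5 * (grad_v + grad_v.T)
    skw = 0.5 * (grad_v - grad_v.T)
    K = strain_relaxation_rate(N, M, c, params)
    return (
        -strain @ skw
        + skw @ strain
        - (np.trace(strain) - 1.0) * sym
        - K * strain
    )
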