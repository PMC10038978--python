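"""Initial-condition generators for the in-silico experiments.

Three families:

* the *wound* scenario — a quarter-domain burn on [0, 3.2]^2 cm^2 with a
  depleted square wound region, a sine-ramp transition to healthy skin, used
  by the mesh-convergence study;
* the *perturbation* scenario — sine/spline perturbations of the healthy
  equilibrium on the unit square, used to probe the stability threshold in
  the signaling-molecule decay rate;
* the *intervention reset* — clamping signaling molecules and/or
  myofibroblasts back to their healthy equilibria mid-run, emulating
  abolishing growth-factor stimulation in a hypertrophic scar.

All generators are deterministic functions of their scenario descriptors.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fem.mesh import TriangleMesh
from .fem.solver import FieldState
from .params import ModelParameters

__all__ = [
    "WoundScenario",
    "PerturbationScenario",
    "wound_initial_conditions",
    "perturbation_initial_conditions",
    "intervention_reset",
    "bump_spline",
]


@dataclass(frozen=True)
class WoundScenario:
    """Square wound inside a quarter domain, sine-ramped to equilibrium."""

    domain_side: float = 3.2  # cm
    wound_side: float = 1.2  # cm
    transition_width: float = 0.8  # cm
    wound_N: float = 2000.0  # cells/cm^3
    wound_c: float = 1.0e-8  # g/cm^3
    wound_rho: float = 1.125e-2  # g/cm^3

    def __post_init__(self) -> None:
        if self.wound_side + self.transition_width > self.domain_side:
            raise ValueError("wound + transition exceed the domain")
        if min(self.wound_N, self.wound_c, self.wound_rho) < 0:
            raise ValueError("wound values must be nonnegative")


@dataclass(frozen=True)
class PerturbationScenario:
    """Wavelike perturbation of the healthy equilibrium on the unit square.

    ``k`` counts the sine waves per side; myofibroblasts and signaling
    molecules use products of piecewise-linear bump splines with 2k+1
    uniform knots (zero at the boundary knots, alternating peak/mid interior
    values), keeping both fields nonnegative.
    """

    k: int = 1
    amp_N: float = 10.0  # cells/cm^3
    amp_rho: float = 1.0e-2  # g/cm^3
    spline_peak_M: float = 3.0  # cells/cm^3
    spline_mid_M: float = 1.0  # cells/cm^3
    spline_peak_c: float = 2.0e-7  # g/cm^3
    spline_mid_c: float = 5.0e-8  # g/cm^3
    amp_v1: float = 5.0e-1  # cm/day

    def __post_init__(self) -> None:
        if self.k < 1:
            raise ValueError("k must be >= 1")


def _wound_profile(s: np.ndarray, wound_side: float, width: float) -> np.ndarray:
    """1 inside the wound interval, sin^2 ramp down to 0 across the
    transition (continuously differentiable at both ends)."""
    d = np.clip((np.asarray(s, float) - wound_side) / width, 0.0, 1.0)
    return np.cos(0.5 * np.pi * d) ** 2


def wound_initial_conditions(
    mesh: TriangleMesh, scenario: WoundScenario, params: ModelParameters
) -> FieldState:
    """Wound values inside the wound square, equilibrium beyond the
    transition, ramped in between by a product of one-dimensional sin^2
    profiles (smooth, so the discrete solution keeps its full convergence
    order); M = 0, v = 0, strain = 0 everywhere."""
    x, y = mesh.coords0[:, 0], mesh.coords0[:, 1]
    w = _wound_profile(x, scenario.wound_side, scenario.transition_width) * \
        _wound_profile(y, scenario.wound_side, scenario.transition_width)

    state = FieldState.at_equilibrium(mesh, params)
    state.N = params.N_bar + (scenario.wound_N - params.N_bar) * w
    state.c = params.c_bar + (scenario.wound_c - params.c_bar) * w
    state.rho = params.rho_bar + (scenario.wound_rho - params.rho_bar) * w
    return state


def bump_spline(x: np.ndarray, k: int, peak: float, mid: float) -> np.ndarray:
    """Piecewise-linear spline through 2k+1 uniform knots on [0, 1]:
    zero at both boundary knots, interior knots alternating peak, mid,
    peak, ... (odd knots peak, even knots mid)."""
    knots = np.linspace(0.0, 1.0, 2 * k + 1)
    values = np.where(np.arange(2 * k + 1) % 2 == 1, peak, mid)
    values[0] = values[-1] = 0.0
    return np.interp(np.asarray(x, float), knots, values)


def perturbation_initial_conditions(
    mesh: TriangleMesh, scenario: PerturbationScenario, params: ModelParameters
) -> FieldState:
    """Sine-product perturbations of N, rho and v; spline-product bumps for
    M and c; v2 = -v1 to preserve the diagonal symmetry; strain zero.

    Every perturbed field respects the boundary conditions exactly: the sine
    products vanish on the outer boundary and on the symmetry normals, and
    the spline products vanish on all boundary knot lines.
    """
    x, y = mesh.coords0[:, 0], mesh.coords0[:, 1]
    k = scenario.k
    wave = np.sin(k * np.pi * x) * np.sin(k * np.pi * y)

    state = FieldState.at_equilibrium(mesh, params)
    state.N = params.N_bar + scenario.amp_N * wave
    state.rho = params.rho_bar + scenario.amp_rho * wave
    # literal product of the two 1-D splines: the effective amplitudes are the
    # squared knot values (e.g. peak (2e-7)^2 = 4e-14 for signaling molecules)
    sM = bump_spline(x, k, scenario.spline_peak_M, scenario.spline_mid_M)
    tM = bump_spline(y, k, scenario.spline_peak_M, scenario.spline_mid_M)
    state.M = sM * tM
    sc = bump_spline(x, k, scenario.spline_peak_c, scenario.spline_mid_c)
    tc = bump_spline(y, k, scenario.spline_peak_c, scenario.spline_mid_c)
    state.c = sc * tc
    state.v1 = scenario.amp_v1 * wave
    state.v2 = -state.v1
    return state


def intervention_reset(
    state: FieldState,
    params: ModelParameters,
    reset_c: bool = False,
    reset_M: bool = False,
) -> FieldState:
    """Clamp selected fields back to the healthy equilibrium everywhere;
    every other field is left bitwise untouched."""
    out = state.copy()
    if reset_c:
        out.c = np.full_like(out.c, params.c_bar)
    if reset_M:
        out.M = np.full_like(out.M, params.M_bar)
    return out
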