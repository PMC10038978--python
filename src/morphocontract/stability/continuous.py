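"""Fourier-mode linear stability of the continuous problem.

Perturbations around the uniform equilibrium
``(N_bar, 0, 0, rho_bar, 0, 0, e11, e12, e22)`` are expanded in complex
Fourier modes ``exp(2 i pi l x) exp(2 i pi p y)`` on the unit square
(|Omega| = 1, hard-coded).  Each wave pair ``(l, p)`` yields a 9x9 linear
system ``y' + A y = 0`` in the coefficient vector ``y``; the model is
linearly stable for that mode iff every eigenvalue of ``A`` has nonnegative
real part.

Matrix convention
-----------------
The code stores ``A`` of ``y' + A y = 0`` — stability means ``Re(lambda) >= 0``.
This is the *negative* of the generator convention ``y' = B y`` used elsewhere
in the literature; both appear in print, so it is stated here once and the
``ModeSystem`` type records it.

Variable ordering: ``(c, M, N, rho, v1, v2, e11, e12, e22)`` — the ordering
that makes the biochemical 4x4 block lower-triangular, so its eigenvalues are
the diagonal entries (the four closed-form "chemical conditions").
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from ..params import ModelParameters, StrainEquilibrium

__all__ = [
    "VARIABLE_ORDER",
    "WaveMode",
    "ModeSystem",
    "StabilityVerdict",
    "StabilityMap",
    "assemble_mode_matrix",
    "chemical_conditions",
    "mechanical_block",
    "mechanical_eigenvalues",
    "stability_indicator",
    "stability_map",
    "stability_verdict",
    "gershgorin_special_equilibrium",
]

VARIABLE_ORDER: tuple[str, ...] = (
    "c", "M", "N", "rho", "v1", "v2", "e11", "e12", "e22",
)

#: Default relative tolerance absorbing round-off in "Re(lambda) >= 0" checks.
DEFAULT_EIG_RTOL = 1e-12


@dataclass(frozen=True)
class WaveMode:
    """An integer Fourier wave pair; (0, 0) is the constant mode."""

    l: int
    p: int


@dataclass(frozen=True)
class ModeSystem:
    """Per-mode linear system ``y' + A y = 0`` (stability iff Re(eig(A)) >= 0)."""

    matrix: np.ndarray
    mode: WaveMode
    kind: str  # "continuous" | "semidiscrete"
    ordering: tuple[str, ...] = VARIABLE_ORDER
    h: float | None = None  # grid spacing, semidiscrete only

    @property
    def mechanical_block(self) -> np.ndarray:
        """The 5x5 submatrix over (v1, v2, e11, e12, e22)."""
        return self.matrix[4:, 4:]

    @property
    def chemical_block(self) -> np.ndarray:
        """The lower-triangular 4x4 submatrix over (c, M, N, rho)."""
        return self.matrix[:4, :4]


@dataclass(frozen=True)
class StabilityVerdict:
    chemical_condition_values: np.ndarray
    mechanical_eigenvalues: np.ndarray
    stable: bool
    tolerance: float


@dataclass(frozen=True)
class StabilityMap:
    """0/1 stability indicator over a grid of strain equilibria.

    ``S[k, i, j]`` is the indicator at ``(e11_axis[i], e22_axis[j],
    e12_levels[k])``.
    """

    e11_axis: np.ndarray
    e22_axis: np.ndarray
    e12_levels: np.ndarray
    S: np.ndarray
    mode_range: tuple[int, int]

    def stable_area(self, level_index: int) -> int:
        return int(self.S[level_index].sum())


# ---------------------------------------------------------------------------
# assembly


def _chemical_entries(params: ModelParameters, k2: float) -> np.ndarray:
    """Lower-triangular 4x4 block over (c, M, N, rho); ``k2`` is the symbol of
    the (negated) Laplacian for the mode, ``(2 pi l)^2 + (2 pi p)^2``."""
    p = params
    Nb, rb = p.N_bar, p.rho_bar
    A = np.zeros((4, 4))
    A[0, 0] = p.D_c * k2 + Nb * (p.delta_c * rb - p.k_c / p.a_c_II)
    A[1, 0] = -p.k_F * Nb
    A[1, 1] = p.D_F * Nb * k2 + p.delta_M
    A[2, 0] = -Nb * p.chi_F * k2 - Nb * (
        p.r_F * p.r_F_max / p.a_c_I * (1.0 - p.kappa_F * Nb) * Nb**p.q - p.k_F
    )
    A[2, 1] = p.r_F * p.kappa_F * Nb ** (1.0 + p.q)
    A[2, 2] = (
        p.D_F * Nb * k2
        - p.r_F * Nb**p.q * ((1.0 + p.q) * (1.0 - p.kappa_F * Nb) - p.kappa_F * Nb)
        + p.delta_N
    )
    A[3, 0] = -p.delta_rho * rb**2 * Nb * (p.k_rho_max / p.a_c_IV + p.a_c_III)
    A[3, 1] = p.delta_rho * rb**2 * (p.eta_II - p.eta_I)
    A[3, 3] = 2.0 * p.delta_rho * Nb * rb
    return A


def _assemble(
    params: ModelParameters,
    strain_eq: StrainEquilibrium,
    wl,
    wp,
    vl,
    vp,
    mixed,
) -> np.ndarray:
    """Shared 9x9 assembly for the continuous and semi-discrete systems.

    ``wl, wp``  — first-derivative symbols (continuous: 2 pi l, 2 pi p),
    ``vl, vp``  — second-derivative symbols (continuous: (2 pi l)^2, ...),
    ``mixed``   — the mixed-derivative symbol of the viscous coupling
    (continuous: (2 pi l)(2 pi p)).
    Arguments may be arrays broadcasting to a common mode-batch shape.
    """
    p = params
    e11, e12, e22 = strain_eq.e11, strain_eq.e12, strain_eq.e22
    wl, wp, vl, vp, mixed = np.broadcast_arrays(
        np.asarray(wl, float), np.asarray(wp, float), np.asarray(vl, float),
        np.asarray(vp, float), np.asarray(mixed, float),
    )
    shape = wl.shape
    A = np.zeros(shape + (9, 9), dtype=complex)
    A[..., :4, :4] = _chemical_entries(params, 0.0)
    k2 = vl + vp
    A[..., 0, 0] += p.D_c * k2
    A[..., 1, 1] += p.D_F * p.N_bar * k2
    A[..., 2, 2] += p.D_F * p.N_bar * k2
    A[..., 2, 0] += -p.N_bar * p.chi_F * k2

    g = p.E * np.sqrt(p.rho_bar) / (1.0 + p.nu)
    nup = p.nu / (1.0 - 2.0 * p.nu)
    trac = p.xi * p.rho_bar / (p.R**2 + p.rho_bar**2)
    grad_rho_1 = (p.E / (2.0 * np.sqrt(p.rho_bar) * (1.0 + p.nu))) * (
        e12 + e11 + nup * (e11 + e22)
    )
    grad_rho_2 = (p.E / (2.0 * np.sqrt(p.rho_bar) * (1.0 + p.nu))) * (
        e12 + e22 + nup * (e11 + e22)
    )
    rt = p.rho_t

    # momentum rows (v1, v2); the full equation is divided by rho_t
    A[..., 4, 1] = -1j * wl * trac / rt
    A[..., 4, 3] = -1j * wl * grad_rho_1 / rt
    A[..., 4, 4] = (vl * (p.mu_1 + p.mu_2) + 0.5 * vp * p.mu_1) / rt
    A[..., 4, 5] = mixed * (0.5 * p.mu_1 + p.mu_2) / rt
    A[..., 4, 6] = -1j * wl * g * (1.0 + nup) / rt
    A[..., 4, 7] = -1j * wp * g / rt
    A[..., 4, 8] = -1j * wl * g * nup / rt

    A[..., 5, 1] = -1j * wp * trac / rt
    A[..., 5, 3] = -1j * wp * grad_rho_2 / rt
    A[..., 5, 4] = A[..., 4, 5]
    A[..., 5, 5] = (vp * (p.mu_1 + p.mu_2) + 0.5 * vl * p.mu_1) / rt
    A[..., 5, 6] = -1j * wp * g * nup / rt
    A[..., 5, 7] = -1j * wl * g / rt
    A[..., 5, 8] = -1j * wp * g * (1.0 + nup) / rt

    # strain rows
    zN = p.zeta * p.N_bar
    A[..., 6, 0] = zN * e11
    A[..., 6, 4] = 1j * (wl * (e11 + e22 - 1.0) - wp * e12)
    A[..., 6, 5] = 1j * wl * e12
    A[..., 7, 0] = zN * e12
    A[..., 7, 4] = 1j * wp * (e11 - 0.5)
    A[..., 7, 5] = 1j * wl * (e22 - 0.5)
    A[..., 8, 0] = zN * e22
    A[..., 8, 4] = 1j * wp * e12
    A[..., 8, 5] = 1j * (wp * (e11 + e22 - 1.0) - wl * e12)
    return A


def assemble_mode_matrix(
    params: ModelParameters,
    strain_eq: StrainEquilibrium,
    mode: WaveMode,
) -> ModeSystem:
    """9x9 continuous per-mode matrix ``A`` of ``y' + A y = 0``."""
    wl, wp = 2.0 * np.pi * mode.l, 2.0 * np.pi * mode.p
    A = _assemble(params, strain_eq, wl, wp, wl**2, wp**2, wl * wp)
    return ModeSystem(matrix=A, mode=mode, kind="continuous")


def chemical_conditions(params: ModelParameters, mode: WaveMode) -> np.ndarray:
    """The four biochemical stability condition values (the diagonal of the
    triangular 4x4 block, ordered N, M, c, rho).  All >= 0 iff the chemical
    part is stable for this mode; diffusion only adds nonnegative terms, so
    stability of the constant mode implies stability of every mode.
    """
    p = params
    k2 = (2.0 * np.pi * mode.l) ** 2 + (2.0 * np.pi * mode.p) ** 2
    A = _chemical_entries(params, k2)
    # order: fibroblast, myofibroblast, signaling molecule, collagen
    return np.array([A[2, 2], A[1, 1], A[0, 0], A[3, 3]])


def mechanical_block(
    params: ModelParameters,
    strain_eq: StrainEquilibrium,
    l: np.ndarray,
    p: np.ndarray,
) -> np.ndarray:
    """Batched 5x5 mechanical blocks for integer mode arrays ``l``, ``p``."""
    wl = 2.0 * np.pi * np.asarray(l, float)
    wp = 2.0 * np.pi * np.asarray(p, float)
    A = _assemble(params, strain_eq, wl, wp, wl**2, wp**2, wl * wp)
    return A[..., 4:, 4:]


def _is_special(strain_eq: StrainEquilibrium) -> bool:
    return strain_eq.as_tuple() == (0.5, 0.0, 0.5)


@dataclass(frozen=True)
class MechanicalSpectrum:
    eigenvalues: np.ndarray  # length 5
    discriminant: float
    closed_form: bool


def mechanical_eigenvalues(
    params: ModelParameters,
    strain_eq: StrainEquilibrium,
    mode: WaveMode,
) -> MechanicalSpectrum:
    """Eigenvalues of the 5x5 mechanical block.

    At the Gershgorin equilibrium (1/2, 0, 1/2) the strain-to-velocity
    coupling vanishes, giving the zero eigenvalue with algebraic multiplicity
    three plus the two real roots of the quadratic of the viscous 2x2 block;
    elsewhere a numerical eigensolve is used.  The quadratic's discriminant
    ``(A55 + A66)^2 - 4 (A55 A66 - A56^2)`` is reported in both branches
    (it is intrinsic to the velocity block and nonnegative for mu1, mu2 >= 0).
    """
    block = mechanical_block(
        params, strain_eq, np.asarray(mode.l), np.asarray(mode.p)
    )
    a55, a66, a56 = block[0, 0].real, block[1, 1].real, block[0, 1].real
    disc = (a55 + a66) ** 2 - 4.0 * (a55 * a66 - a56**2)
    if _is_special(strain_eq):
        sq = np.sqrt(max(disc, 0.0))
        lam = np.array(
            [0.0, 0.0, 0.0, 0.5 * (a55 + a66 - sq), 0.5 * (a55 + a66 + sq)],
            dtype=complex,
        )
        return MechanicalSpectrum(lam, float(disc), True)
    lam = np.linalg.eigvals(block)
    return MechanicalSpectrum(np.sort_complex(lam), float(disc), False)


def _mode_lattice(l_max: int, p_max: int) -> tuple[np.ndarray, np.ndarray]:
    l, p = np.meshgrid(
        np.arange(1, l_max + 1), np.arange(1, p_max + 1), indexing="ij"
    )
    return l.ravel(), p.ravel()


def _min_real_eig(blocks: np.ndarray) -> float:
    """Smallest real part over the spectra of a stack of blocks."""
    return float(np.linalg.eigvals(blocks).real.min())


def _block_tolerance(blocks: np.ndarray, rtol: float) -> float:
    scale = np.abs(blocks).max()
    return rtol * max(scale, 1.0)


def stability_verdict(
    params: ModelParameters,
    strain_eq: StrainEquilibrium,
    mode: WaveMode,
    rtol: float = DEFAULT_EIG_RTOL,
) -> StabilityVerdict:
    """Combined chemical + mechanical verdict for a single wave pair."""
    chem = chemical_conditions(params, mode)
    spec = mechanical_eigenvalues(params, strain_eq, mode)
    block = mechanical_block(params, strain_eq, np.asarray(mode.l), np.asarray(mode.p))
    tol = _block_tolerance(block, rtol)
    stable = bool(
        np.all(chem >= -tol) and np.all(spec.eigenvalues.real >= -tol)
    )
    return StabilityVerdict(chem, spec.eigenvalues, stable, tol)


def stability_indicator(
    params: ModelParameters,
    strain_eq: StrainEquilibrium,
    l_max: int = 100,
    p_max: int = 100,
    rtol: float = DEFAULT_EIG_RTOL,
) -> int:
    """The 0/1 indicator S over wavelike perturbations.

    S = 1 iff every eigenvalue of the 5x5 mechanical block has real part
    >= -tolerance for all integer wave pairs ``l in [1, l_max]``,
    ``p in [1, p_max]`` (the empirical sweep range); the sign symmetry of the
    mode matrix makes negative wave numbers redundant.
    """
    if l_max < 1 or p_max < 1:
        raise ValueError("mode range must include at least (1, 1)")
    l, p = _mode_lattice(l_max, p_max)
    blocks = mechanical_block(params, strain_eq, l, p)
    tol = _block_tolerance(blocks, rtol)
    return int(_min_real_eig(blocks) >= -tol)


def stability_map(
    params: ModelParameters,
    e11_grid: np.ndarray,
    e22_grid: np.ndarray,
    e12_levels: np.ndarray,
    mode_range: tuple[int, int] = (100, 100),
    rtol: float = DEFAULT_EIG_RTOL,
) -> StabilityMap:
    """Evaluate S on a grid of strain equilibria for several e12 levels.

    The published sweep uses e11, e22 on [-1, 1] with step 0.01 and wave
    numbers up to 100; coarser grids give the same qualitative picture at a
    fraction of the cost and are used in the test suite.
    """
    e11_grid = np.asarray(e11_grid, float)
    e22_grid = np.asarray(e22_grid, float)
    e12_levels = np.atleast_1d(np.asarray(e12_levels, float))
    l, p = _mode_lattice(*mode_range)
    S = np.zeros((e12_levels.size, e11_grid.size, e22_grid.size), dtype=int)
    for k, e12 in enumerate(e12_levels):
        for i, e11 in enumerate(e11_grid):
            for j, e22 in enumerate(e22_grid):
                eq = StrainEquilibrium(e11, e12, e22)
                blocks = mechanical_block(params, eq, l, p)
                tol = _block_tolerance(blocks, rtol)
                S[k, i, j] = int(_min_real_eig(blocks) >= -tol)
    return StabilityMap(e11_grid, e22_grid, e12_levels, S, mode_range)


def gershgorin_special_equilibrium() -> StrainEquilibrium:
    """The unique strain triple making every Gershgorin disk of the
    strain-to-velocity coupling degenerate for all integer wave pairs.

    Solves, for all (alpha, beta):

        |alpha| (e11 + e12 + e22 - 1) - |beta| e12 = 0
        |alpha| (e11 - 1/2) + |beta| (e22 - 1/2) = 0

    assembled from the independent pairs (1,0), (0,1), (1,1) as a small
    least-squares system; the exact solution is (1/2, 0, 1/2).
    """
    rows, rhs = [], []
    for a, b in ((1, 0), (0, 1), (1, 1)):
        rows.append([a, a - b, a])
        rhs.append(a)
        rows.append([a, 0.0, b])
        rhs.append(0.5 * (a + b))
    sol, *_ = np.linalg.lstsq(np.array(rows, float), np.array(rhs, float), rcond=None)
    return StrainEquilibrium(*np.round(sol, 12))
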