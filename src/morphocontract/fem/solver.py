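"""Moving-grid FEM solver for the fully nonlinear contraction model.

Discretization choices:

* linear (P1) triangles on a cross-divided quadrilateral mesh;
* vertex-rule (Newton-Cotes) quadrature and row-sum mass lumping, which
  preserves monotonicity of the backward Euler stepping;
* backward Euler in time, one monolithic linear system per Picard iteration
  with the nonlinear coefficients frozen at the previous iterate;
* the mesh moves with the displacement velocity: inside the Picard loop the
  trial mesh is ``x^n + dt * v`` with the current velocity iterate, so the
  converged step uses the end-of-step velocity (first iterate: ``v^n``);
* no boundary conditions on collagen and strain (their equations carry no
  spatial derivatives of their own unknowns); far-field Dirichlet data on
  the outer boundary, symmetry conditions (``v . n = 0`` strongly, zero
  normal flux and zero tangential traction naturally) on the axes;
* mesh quality is monitored as min|J|/max|J|; below 0.5 the run halts with
  a diagnostic instead of remeshing.

The moving-mesh (ALE) time derivative uses the transport identity
``d/dt int z phi = int (Dz/Dt + z div v) phi`` for basis functions advected
with the mesh, so conservation-form equations need no explicit convection
terms; the strain equation, which is *not* in conservation form, gets the
compensating ``- z div v`` correction.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import sparse
from scipy.sparse.linalg import splu

from ..params import ModelParameters
from .assemble import Geometry
from .mesh import TriangleMesh, mesh_quality

__all__ = [
    "FIELD_NAMES",
    "FieldState",
    "TimeStepperConfig",
    "PicardConfig",
    "StepInfo",
    "SimulationResult",
    "ConvergenceReport",
    "Simulator",
    "step",
    "simulate",
    "time_step_controller",
    "l2_error",
    "convergence_study",
]

FIELD_NAMES = ("N", "M", "c", "rho", "v1", "v2", "e11", "e12", "e21", "e22")
#: the nine physical unknowns reported externally (e21 mirrors e12)
REPORT_FIELDS = ("N", "M", "c", "rho", "v1", "v2", "e11", "e12", "e22")

# characteristic magnitudes used to (column-)scale the monolithic system and
# as floors of the scaled relative-update norm; cell densities ~ N_bar,
# concentrations ~ the Hill half-max scale, mechanics O(0.1)
_FIELD_SCALES = {
    "N": 1.0e4, "M": 1.0e4, "c": 1.0e-8, "rho": 1.0e-1,
    "v1": 1.0e-1, "v2": 1.0e-1, "e11": 1.0e-1, "e12": 1.0e-1,
    "e21": 1.0e-1, "e22": 1.0e-1,
}


@dataclass
class FieldState:
    """Nodal unknowns plus accumulated displacement on the moving mesh."""

    N: np.ndarray
    M: np.ndarray
    c: np.ndarray
    rho: np.ndarray
    v1: np.ndarray
    v2: np.ndarray
    e11: np.ndarray
    e12: np.ndarray
    e21: np.ndarray
    e22: np.ndarray
    u: np.ndarray  # (n_nodes, 2)
    t: float = 0.0

    @classmethod
    def at_equilibrium(cls, mesh: TriangleMesh, params: ModelParameters) -> "FieldState":
        n = mesh.n_nodes
        z = np.zeros(n)
        return cls(
            N=np.full(n, params.N_bar), M=np.full(n, params.M_bar),
            c=np.full(n, params.c_bar), rho=np.full(n, params.rho_bar),
            v1=z.copy(), v2=z.copy(), e11=z.copy(), e12=z.copy(),
            e21=z.copy(), e22=z.copy(), u=np.zeros((n, 2)), t=0.0,
        )

    def get(self, name: str) -> np.ndarray:
        return getattr(self, name)

    def copy(self) -> "FieldState":
        return FieldState(
            **{name: self.get(name).copy() for name in FIELD_NAMES},
            u=self.u.copy(), t=self.t,
        )

    def vector(self) -> np.ndarray:
        return np.concatenate([self.get(name) for name in FIELD_NAMES])


@dataclass(frozen=True)
class TimeStepperConfig:
    """Published stepping protocol: dt = 1e-2 day until half a day, then
    dt_new = min(dt_cap, growth_factor * dt); ``fixed_dt`` overrides
    everything (convergence studies use dt = h^2)."""

    dt_initial: float = 1.0e-2
    switch_time: float = 0.5
    growth_factor: float = 1.1
    dt_cap: float = 2.0
    fixed_dt: float | None = None

    def __post_init__(self) -> None:
        if self.dt_initial <= 0:
            raise ValueError("dt_initial must be positive")
        if self.growth_factor < 1.0:
            raise ValueError("growth_factor must be >= 1")


@dataclass(frozen=True)
class PicardConfig:
    relative_tolerance: float = 1.0e-6
    max_iterations: int = 25

    def __post_init__(self) -> None:
        if self.relative_tolerance <= 0 or self.max_iterations < 1:
            raise ValueError("invalid Picard configuration")


@dataclass
class StepInfo:
    picard_iterations: int
    converged: bool
    quality: float
    negative_nodes: dict[str, int]


@dataclass
class SimulationResult:
    times: np.ndarray
    quality_trace: np.ndarray
    picard_trace: np.ndarray
    tracked_points: dict[int, dict[str, np.ndarray]]  # node index -> traces
    snapshots: list[tuple[float, FieldState]]
    status: str  # completed | quality_halt | picard_halt
    final_state: FieldState
    mesh: TriangleMesh

    @property
    def min_quality(self) -> float:
        return float(self.quality_trace.min()) if self.quality_trace.size else 1.0


@dataclass
class ConvergenceReport:
    h_values: np.ndarray
    h_track: float
    errors: dict[str, np.ndarray]  # per variable, one entry per non-reference h
    slopes: dict[str, float]

    def as_table(self):
        import pandas as pd

        rows = {var: list(errs) + [self.slopes[var]] for var, errs in self.errors.items()}
        index = [f"h={h:g}" for h in self.h_values[:-1]] + ["slope"]
        return pd.DataFrame(rows, index=index)


def time_step_controller(t: float, dt_prev: float, cfg: TimeStepperConfig) -> float:
    """Next time step per the adaptive protocol (see TimeStepperConfig)."""
    if cfg.fixed_dt is not None:
        return cfg.fixed_dt
    if t < cfg.switch_time - 1e-12:
        return cfg.dt_initial
    return min(cfg.dt_cap, cfg.growth_factor * dt_prev)


def l2_error(z_h: np.ndarray, z_ref: np.ndarray, h: float) -> float:
    """Discrete L2 error h * sqrt(sum (z_h - z_ref)^2) over the tracked
    coarse-grid points; ``h`` is the spacing of the run that produced
    ``z_h`` (the error measure of the mesh-refinement study)."""
    z_h = np.asarray(z_h, float)
    z_ref = np.asarray(z_ref, float)
    if z_h.shape != z_ref.shape:
        raise ValueError("mismatched point counts in l2_error")
    return float(h * np.sqrt(np.sum((z_h - z_ref) ** 2)))


class PicardDivergence(RuntimeError):
    """Inner Picard iterations failed to converge."""


class QualityError(RuntimeError):
    """Mesh quality dropped below the remeshing threshold 0.5."""


def _pow_guard(x: np.ndarray, expo: float) -> np.ndarray:
    """x**expo where x > 0, else 0 (negative densities are diagnostics,
    never fed to fractional powers)."""
    out = np.zeros_like(x)
    pos = x > 0.0
    out[pos] = x[pos] ** expo
    return out


class Simulator:
    """Owns the reference mesh, parameters and numerical configuration."""

    def __init__(
        self,
        mesh: TriangleMesh,
        params: ModelParameters,
        picard: PicardConfig | None = None,
        stepper: TimeStepperConfig | None = None,
    ):
        self.mesh0 = mesh
        self.params = params
        self.picard = picard or PicardConfig()
        self.stepper = stepper or TimeStepperConfig()
        self._idx_o = np.flatnonzero(mesh.gamma_o)
        self._idx_h = np.flatnonzero(mesh.gamma_h & ~mesh.gamma_o)
        self._idx_v = np.flatnonzero(mesh.gamma_v & ~mesh.gamma_o)
        self._n = mesh.n_nodes

    # -- helpers ----------------------------------------------------------

    def current_mesh(self, state: FieldState) -> TriangleMesh:
        return self.mesh0.moved(state.u)

    def _dirichlet(self) -> list[tuple[str, np.ndarray, float]]:
        p = self.params
        return [
            ("N", self._idx_o, p.N_bar),
            ("M", self._idx_o, p.M_bar),
            ("c", self._idx_o, p.c_bar),
            ("v1", self._idx_o, 0.0),
            ("v2", self._idx_o, 0.0),
            ("v1", self._idx_v, 0.0),
            ("v2", self._idx_h, 0.0),
        ]

    def _assemble(self, geo: Geometry, m_old: np.ndarray, old: FieldState,
                  star: FieldState, dt: float):
        """One monolithic backward-Euler system with coefficients frozen at
        the Picard iterate ``star``; returns (csr matrix, rhs)."""
        p = self.params
        n = self._n
        m1 = geo.lumped
        Ns, Ms, cs, rs = star.N, star.M, star.c, star.rho
        if np.any(1.0 + p.a_c_III * cs <= 0) or np.any(p.a_c_I + cs <= 0) or np.any(
            p.a_c_II + cs <= 0
        ) or np.any(p.a_c_IV + cs <= 0):
            raise PicardDivergence("Hill denominator left its domain")

        blocks: dict[tuple[int, int], sparse.spmatrix] = {}
        rhs = {name: np.zeros(n) for name in FIELD_NAMES}
        fi = {name: k for k, name in enumerate(FIELD_NAMES)}

        def add(row: str, col: str, matrix) -> None:
            key = (fi[row], fi[col])
            blocks[key] = matrix if key not in blocks else blocks[key] + matrix

        def diag(vec) -> sparse.csr_matrix:
            return sparse.diags(vec).tocsr()

        crowd = 1.0 - p.kappa_F * (Ns + Ms)
        hill_div = cs / (p.a_c_I + cs)
        mmp = (Ns + p.eta_II * Ms) / (1.0 + p.a_c_III * cs)

        # fibroblasts: diffusion + chemotaxis + logistic/differentiation/apoptosis
        alpha_N = (
            p.r_F * (1.0 + p.r_F_max * hill_div) * crowd * _pow_guard(Ns, p.q)
            - p.k_F * cs - p.delta_N
        )
        add("N", "N", diag(m1 / dt - m1 * alpha_N) + geo.stiffness(p.D_F * (Ns + Ms)))
        add("N", "c", -geo.stiffness(p.chi_F * Ns))
        rhs["N"] += m_old * old.N / dt

        # myofibroblasts: signal-dependent proliferation (explicit), diff. source
        add("M", "M", diag(m1 / dt + m1 * p.delta_M) + geo.stiffness(p.D_F * (Ns + Ms)))
        add("M", "c", -geo.stiffness(p.chi_F * Ms))
        add("M", "N", diag(-m1 * p.k_F * cs))
        rhs["M"] += m_old * old.M / dt + m1 * (
            p.r_F * (1.0 + p.r_F_max) * hill_div * crowd * _pow_guard(Ms, 1.0 + p.q)
        )

        # signaling molecules: diffusion, secretion (linearized), MMP decay
        gamma_c = p.delta_c * mmp * rs - p.k_c * (Ns + p.eta_I * Ms) / (p.a_c_II + cs)
        add("c", "c", diag(m1 / dt + m1 * gamma_c) + geo.stiffness(p.D_c))
        rhs["c"] += m_old * old.c / dt

        # collagen: pointwise secretion/decay, no spatial operator
        add("rho", "rho", diag(m1 / dt + m1 * p.delta_rho * mmp * rs))
        rhs["rho"] += m_old * old.rho / dt + m1 * (
            p.k_rho * (1.0 + p.k_rho_max * cs / (p.a_c_IV + cs)) * (Ns + p.eta_I * Ms)
        )

        # momentum: viscous + elastic stress, myofibroblast traction body force
        Kdir = {
            (a, b): self._dir_stiffness(geo, a, b)
            for a in (0, 1) for b in (0, 1)
        }
        mu1, mu2 = p.mu_1, p.mu_2
        add("v1", "v1", diag(p.rho_t * m1 / dt) + (mu1 + mu2) * Kdir[0, 0] + 0.5 * mu1 * Kdir[1, 1])
        add("v1", "v2", mu2 * Kdir[1, 0] + 0.5 * mu1 * Kdir[0, 1])
        add("v2", "v1", mu2 * Kdir[0, 1] + 0.5 * mu1 * Kdir[1, 0])
        add("v2", "v2", diag(p.rho_t * m1 / dt) + (mu1 + mu2) * Kdir[1, 1] + 0.5 * mu1 * Kdir[0, 0])

        g_stiff = p.E * np.sqrt(np.clip(rs, 0.0, None)) / (1.0 + p.nu)
        nup = p.nu / (1.0 - 2.0 * p.nu)
        Dx_g = geo.gradient_op(0, g_stiff)
        Dy_g = geo.gradient_op(1, g_stiff)
        add("v1", "e11", (1.0 + nup) * Dx_g)
        add("v1", "e22", nup * Dx_g)
        add("v1", "e12", Dy_g)
        add("v2", "e21", Dx_g)
        add("v2", "e11", nup * Dy_g)
        add("v2", "e22", (1.0 + nup) * Dy_g)

        psi = p.xi * Ms * rs / (p.R**2 + rs**2)
        rhs["v1"] += p.rho_t * m_old * old.v1 / dt - geo.gradient_op(0) @ psi
        rhs["v2"] += p.rho_t * m_old * old.v2 / dt - geo.gradient_op(1) @ psi

        # effective strain: pointwise morphoelastic law, weak nodal gradients
        Gx = geo.gradient_op(0).T.tocsr()  # int phi_i d_x(.)
        Gy = geo.gradient_op(1).T.tocsr()
        div_star = (Gx @ star.v1 + Gy @ star.v2) / m1
        relax = p.zeta * (Ns + p.eta_II * Ms) * cs / (1.0 + p.a_c_III * cs)
        strain_diag = diag(m1 / dt - m1 * div_star + m1 * relax)
        off = 0.5 * (star.e12 + star.e21)
        trm1 = star.e11 + star.e22 - 1.0
        for comp in ("e11", "e12", "e21", "e22"):
            add(comp, comp, strain_diag)
            rhs[comp] += m_old * old.get(comp) / dt
        add("e11", "v1", diag(trm1) @ Gx - diag(off) @ Gy)
        add("e11", "v2", diag(off) @ Gx)
        add("e12", "v1", diag(star.e11 - 0.5) @ Gy)
        add("e12", "v2", diag(star.e22 - 0.5) @ Gx)
        add("e21", "v1", diag(star.e11 - 0.5) @ Gy)
        add("e21", "v2", diag(star.e22 - 0.5) @ Gx)
        add("e22", "v1", diag(off) @ Gy)
        add("e22", "v2", diag(trm1) @ Gy - diag(off) @ Gx)

        # assemble the 10x10 block matrix
        grid = [[blocks.get((i, j)) for j in range(10)] for i in range(10)]
        A = sparse.bmat(grid, format="csr")
        b = np.concatenate([rhs[name] for name in FIELD_NAMES])

        # Dirichlet by row replacement
        rows, vals = [], []
        for name, idx, value in self._dirichlet():
            rows.append(fi[name] * n + idx)
            vals.append(np.full(idx.size, value))
        rows = np.concatenate(rows)
        vals = np.concatenate(vals)
        zero_rows(A, rows)
        A = A + sparse.coo_matrix(
            (np.ones(rows.size), (rows, rows)), shape=A.shape
        ).tocsr()
        b[rows] = vals
        return A, b

    @staticmethod
    def _dir_stiffness(geo: Geometry, k: int, l: int) -> sparse.csr_matrix:
        """int d_k phi_j d_l phi_i (constant-coefficient directional stiffness)."""
        gb = geo.grads[:, :, k]
        ga = geo.grads[:, :, l]
        vals = geo.area[:, None, None] * ga[:, :, None] * gb[:, None, :]
        return geo._coo(vals)

    # -- stepping ---------------------------------------------------------

    def step(self, state: FieldState, dt: float) -> tuple[FieldState, StepInfo]:
        """One backward-Euler step with inner Picard iterations."""
        if dt <= 0:
            raise ValueError("dt must be positive")
        mesh_old = self.current_mesh(state)
        q_old = mesh_quality(mesh_old)
        if q_old < 0.5:
            raise QualityError("mesh quality below 0.5; remeshing not supported")
        m_old = Geometry(mesh_old).lumped

        star = state.copy()
        n = self._n
        for iteration in range(1, self.picard.max_iterations + 1):
            u_trial = state.u + dt * np.column_stack([star.v1, star.v2])
            mesh_new = self.mesh0.moved(u_trial)
            if np.any(mesh_new.signed_jacobians() <= 0.0):
                raise PicardDivergence("mesh tangling during Picard iteration")
            geo = Geometry(mesh_new)
            A, b = self._assemble(geo, m_old, state, star, dt)
            # equilibrate: column-scale to O(1) unknowns (so round-off cannot
            # leak from cell-density rows into the tiny concentrations), then
            # row-scale to O(1) equations
            scale = np.repeat([_FIELD_SCALES[f] for f in FIELD_NAMES], n)
            Ac = (A @ sparse.diags(scale)).tocsr()
            rinv = 1.0 / np.maximum.reduceat(np.abs(Ac.data), Ac.indptr[:-1])
            Ac = sparse.diags(rinv) @ Ac
            sol = scale * splu(Ac.tocsc()).solve(rinv * b)
            new = FieldState(
                **{name: sol[k * n:(k + 1) * n] for k, name in enumerate(FIELD_NAMES)},
                u=u_trial, t=state.t + dt,
            )
            err = self._relative_update(star, new)
            star = new
            if err < self.picard.relative_tolerance:
                break
        else:
            raise PicardDivergence(
                f"Picard did not reach tolerance in {self.picard.max_iterations} iterations"
            )
        # final displacement update with the converged velocity
        star.u = state.u + dt * np.column_stack([star.v1, star.v2])
        mesh_final = self.mesh0.moved(star.u)
        info = StepInfo(
            picard_iterations=iteration,
            converged=True,
            quality=mesh_quality(mesh_final),
            negative_nodes={
                name: int(np.sum(star.get(name) < 0.0))
                for name in ("N", "M", "c", "rho")
            },
        )
        return star, info

    @staticmethod
    def _relative_update(prev: FieldState, new: FieldState) -> float:
        err = 0.0
        for name in FIELD_NAMES:
            a, b = prev.get(name), new.get(name)
            scale = max(float(np.abs(b).max()), _FIELD_SCALES[name])
            err = max(err, float(np.abs(a - b).max()) / scale)
        return err

    # -- full runs --------------------------------------------------------

    def run(
        self,
        state: FieldState,
        T: float,
        track_points: list[tuple[float, float]] | None = None,
        snapshot_times: list[float] | None = None,
    ) -> SimulationResult:
        """Advance to time ``T`` or halt (quality < 0.5 / Picard failure)."""
        track_idx = [self._nearest_node(xy) for xy in (track_points or [])]
        traces: dict[int, dict[str, list[float]]] = {
            i: {name: [] for name in FIELD_NAMES + ("x", "y")} for i in track_idx
        }
        times, qualities, picards = [], [], []
        snapshots: list[tuple[float, FieldState]] = []
        want_snaps = sorted(snapshot_times or [])
        status = "completed"
        dt_prev = self.stepper.fixed_dt or self.stepper.dt_initial
        while state.t < T - 1e-9:
            dt = min(time_step_controller(state.t, dt_prev, self.stepper),
                     T - state.t)
            try:
                state, info = self.step(state, dt)
            except PicardDivergence:
                status = "picard_halt"
                break
            except QualityError:
                status = "quality_halt"
                break
            dt_prev = max(dt, dt_prev)
            times.append(state.t)
            qualities.append(info.quality)
            picards.append(info.picard_iterations)
            mesh_now = self.current_mesh(state)
            for i in track_idx:
                for name in FIELD_NAMES:
                    traces[i][name].append(float(state.get(name)[i]))
                traces[i]["x"].append(float(mesh_now.coords[i, 0]))
                traces[i]["y"].append(float(mesh_now.coords[i, 1]))
            while want_snaps and state.t >= want_snaps[0] - 1e-9:
                snapshots.append((state.t, state.copy()))
                want_snaps.pop(0)
            if info.quality < 0.5:
                status = "quality_halt"
                break
        return SimulationResult(
            times=np.asarray(times),
            quality_trace=np.asarray(qualities),
            picard_trace=np.asarray(picards),
            tracked_points={
                i: {k: np.asarray(v) for k, v in tr.items()} for i, tr in traces.items()
            },
            snapshots=snapshots,
            status=status,
            final_state=state,
            mesh=self.current_mesh(state),
        )

    def _nearest_node(self, xy: tuple[float, float]) -> int:
        d2 = np.sum((self.mesh0.coords0 - np.asarray(xy)) ** 2, axis=1)
        return int(np.argmin(d2))


# -- module-level functional wrappers ---------------------------------------


def step(
    state: FieldState,
    dt: float,
    params: ModelParameters,
    mesh: TriangleMesh,
    picard: PicardConfig | None = None,
) -> tuple[FieldState, StepInfo]:
    return Simulator(mesh, params, picard=picard).step(state, dt)


def simulate(
    initial_state: FieldState,
    mesh: TriangleMesh,
    params: ModelParameters,
    T: float,
    stepper: TimeStepperConfig | None = None,
    picard: PicardConfig | None = None,
    track_points: list[tuple[float, float]] | None = None,
    snapshot_times: list[float] | None = None,
) -> SimulationResult:
    sim = Simulator(mesh, params, picard=picard, stepper=stepper)
    return sim.run(initial_state, T, track_points=track_points,
                   snapshot_times=snapshot_times)


def zero_rows(A: sparse.csr_matrix, rows: np.ndarray) -> None:
    """Zero the given rows of a CSR matrix in place."""
    for r in rows:
        A.data[A.indptr[r]:A.indptr[r + 1]] = 0.0


def convergence_study(
    h_list,
    params: ModelParameters,
    domain: float = 3.2,
    wound_side: float = 1.2,
    T: float = 1.0,
    picard: PicardConfig | None = None,
) -> ConvergenceReport:
    """Mesh-refinement study on the wound scenario.

    Each spacing ``h`` runs the wound protocol on [0, domain]^2 with fixed
    dt = h^2 up to day ``T``; the finest run is the reference.  Errors are
    the discrete L2 norms ``h sqrt(sum (z_h - z_ref)^2)`` over the material
    points that start at the coarsest grid's lattice nodes (each run
    weighted by its own spacing), and slopes are least-squares fits of
    log error against log h (reference excluded).
    """
    from ..scenarios import WoundScenario, wound_initial_conditions
    from .mesh import build_mesh

    h_values = np.asarray(sorted(h_list, reverse=True), float)
    if h_values.size < 2:
        raise ValueError("need at least two spacings")
    h_track = float(h_values[0])
    scenario = WoundScenario(domain_side=domain, wound_side=wound_side)
    axis = np.arange(0.0, domain + 0.5 * h_track, h_track)
    gx, gy = np.meshgrid(axis, axis, indexing="ij")
    track_xy = np.column_stack([gx.ravel(), gy.ravel()])

    solutions = []
    for h in h_values:
        mesh = build_mesh(domain, h)
        state0 = wound_initial_conditions(mesh, scenario, params)
        sim = Simulator(
            mesh, params, picard=picard,
            stepper=TimeStepperConfig(fixed_dt=h * h),
        )
        result = sim.run(state0, T)
        if result.status != "completed":
            raise RuntimeError(f"h={h}: run halted with status {result.status}")
        # material points that started on the tracked lattice
        idx = _match_nodes(mesh.coords0, track_xy)
        solutions.append(
            {name: result.final_state.get(name)[idx] for name in REPORT_FIELDS}
        )

    errors: dict[str, np.ndarray] = {}
    slopes: dict[str, float] = {}
    ref = solutions[-1]
    for name in REPORT_FIELDS:
        errs = np.array(
            [
                l2_error(sol[name], ref[name], float(h))
                for sol, h in zip(solutions[:-1], h_values[:-1])
            ]
        )
        errors[name] = errs
        if errs.size >= 2 and np.all(errs > 0.0):
            slopes[name] = float(
                np.polyfit(np.log(h_values[:-1]), np.log(errs), 1)[0]
            )
        else:
            slopes[name] = float("nan")
    return ConvergenceReport(h_values=h_values, h_track=h_track,
                             errors=errors, slopes=slopes)


def _match_nodes(coords: np.ndarray, targets: np.ndarray) -> np.ndarray:
    """Indices of mesh nodes coinciding with the target points (exact lattice
    nesting assumed)."""
    idx = np.empty(targets.shape[0], dtype=np.int64)
    for k, xy in enumerate(targets):
        d2 = np.sum((coords - xy) ** 2, axis=1)
        j = int(np.argmin(d2))
        if d2[j] > 1e-16:
            raise ValueError("tracked point does not coincide with a mesh node")
        idx[k] = j
    return idx
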