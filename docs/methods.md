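# Methods

## The model

The package implements a two-dimensional biomorphoelastic model of post-burn
skin contraction.  Nine coupled unknowns live on a moving tissue domain:
fibroblasts `N` (cells/cm³), myofibroblasts `M` (cells/cm³), a lumped
signaling-molecule concentration `c` (g/cm³), collagen `ρ` (g/cm³), the
displacement velocity `v = (v₁, v₂)` (cm/day) and the effective (elastic)
strain tensor `ε` (dimensionless, symmetric).  The biochemical species obey
advection–diffusion–reaction laws (chemotaxis of both cell types up the
signal gradient, logistic-like division with Hill-type signal enhancement,
signal-driven differentiation of fibroblasts into myofibroblasts, secretion
and MMP-mediated breakdown of signal and collagen, with the MMP pool assumed
at local equilibrium so its effect enters through a `1/(1 + a_c^III c)`
inhibition factor).  The momentum balance keeps the inertial terms and uses
a visco-elastic Cauchy stress

    σ = μ₁ sym(∇v) + μ₂ tr(sym(∇v)) I + (E√ρ)/(1+ν) [ε + ν/(1−2ν) tr(ε) I],

with a stiffness that scales with the square root of the collagen density,
driven by an isotropic myofibroblast traction potential ξMρ/(R²+ρ²).
Morphoelasticity enters through the strain evolution law

    Dε/Dt + ε skw(∇v) − skw(∇v) ε + (tr ε − 1) sym(∇v) = −K ε,
    K = ζ [N + η^II M] c / (1 + a_c^III c),

which lets contraction become permanent.  All 33 parameters (units cm, day,
g, cells, N) ship as a bundled YAML file; the defaults are the published
simulation values.  Two of them are consequences of the others: the
fibroblast apoptosis rate must balance division at equilibrium
(`δ_N = r_F(1−κ_F N̄)N̄^q`, satisfied by the printed values to ~3·10⁻⁴
relative) and the collagen equilibrium fixes `k_ρ = δ_ρ ρ̄²`
(`ρ̄ = √(k_ρ/δ_ρ) = 0.1125 g/cm³`).  `ModelParameters.consistent()` re-derives
both to machine precision for tests that need an exact fixed point.

## Linear stability

Perturbations of the uniform equilibrium `(N̄, 0, 0, ρ̄, 0, 0, ε̄)` on the
unit square are expanded in Fourier modes `exp(2πi l x) exp(2πi p y)`.  Each
wave pair yields a 9×9 system `y' + A y = 0` in the ordering
`(c, M, N, ρ, v₁, v₂, ε₁₁, ε₁₂, ε₂₂)`; stability means every eigenvalue of
`A` has nonnegative real part.  (The code stores `A`, not the negated
generator — both conventions appear in the literature.)  The biochemical
4×4 block is lower-triangular, so its four eigenvalues are closed-form
diagonal entries; their nonnegativity reduces to two parameter conditions
independent of the wave pair: `δ_c ρ̄ ≥ k_c/a_c^II` (the decay rate of the
signaling molecules is the bifurcation parameter) and
`q δ_N ≤ κ_F r_F N̄^{1+q}`.  Diffusion only adds nonnegative terms, so
stability of the constant mode implies stability of every mode.

The mechanical 5×5 block always has a zero eigenvalue (its three strain
columns act only through the two velocity rows).  At the special strain
equilibrium `(1/2, 0, 1/2)` — the unique triple that makes the
strain-to-velocity coupling vanish for all wave pairs, found via Gershgorin
disks — the zero eigenvalue has algebraic multiplicity three and the
remaining two eigenvalues are the real, nonnegative roots of the quadratic
of the viscous velocity block.  For general strain equilibria no closed form
exists; the 0/1 indicator `S(ε̄₁₁, ε̄₂₂, ε̄₁₂)` is evaluated by a batched
numerical eigensolve over integer wave pairs `l, p ∈ [1, 100]` (the
published empirical sweep range).  The numerical tolerance for
"Re λ ≥ 0" is `−10⁻¹² · max(1, ‖A‖_max)`, configurable; it absorbs the
round-off perturbation of the structural zero eigenvalue, which is orders of
magnitude smaller than any genuine instability we observed (genuinely
unstable triples show `min Re λ` of order −10⁻²…−1, the perturbed zeros
order −10⁻¹²·‖A‖·ε_mach).

The semi-discrete (von Neumann) analysis replaces the derivative symbols by
their central-difference counterparts, `(2πl)² → 4sin²(πlh)/h²`,
`2πl → sin(2πlh)/h`, `(2πl)(2πp) → sin(2πlh)sin(2πph)/h²`, on a grid with
`(n+1)h = 1`.  The matrix is assembled in the same Fourier sign convention
as the continuous one so that the entrywise `h → 0` limit recovers it
exactly; the opposite convention merely conjugates the matrix and leaves the
spectrum unchanged.  Because every discrete diffusion symbol is a smaller
nonnegative number than its continuous counterpart, continuous stability
implies semi-discrete stability for every `h`.  The mechanical determinant
condition is computed directly from the assembled entries as
`(C₅₅C₆₆ − C₅₆²)(ρ_t h²)²`, a homogeneous quadratic in `(μ₁, μ₂)` with
nonnegative trigonometric coefficients.  The gap between matched continuous
and semi-discrete chemical eigenvalues is `O(h²)` with leading coefficient
`D (4π⁴/3)(l⁴+p⁴)`; matching uses the shared closed forms of the triangular
block, never nearest-neighbor pairing.  Scalar amplification factors
`|1/(1+λΔt)|` (backward Euler) and `|(1−λΔt/2)/(1+λΔt/2)|` (trapezoid) are
both ≤ 1 whenever `Re λ ≥ 0`, so the stable equilibria are unconditionally
stable under either time integrator.

Strain-symmetry dynamics: the skew part `ω = ε − εᵀ` obeys a closed 4×4
linear system whose spectrum has constant real part `K`; symmetry is an
invariant of the flow (initially symmetric strain stays symmetric), and it
is null-stable for `K = 0`, asymptotically stable for `K > 0` and unstable
for `K < 0` (expansion).  `‖ω‖` obeys `d‖ω‖/dt = −K(t)‖ω‖` exactly.

## Finite-element solver

The solver validates the stability predictions on the fully nonlinear
system.  Discretization choices:

* **Mesh** — `[0, L]²` divided into square cells of side `h`, each
  cross-divided into four triangles through its centroid; linear (P1)
  Lagrange elements.  Basis functions are advected with the mesh, so their
  material derivative vanishes and the transport identity
  `d/dt ∫ z φ = ∫ (Dz/Dt + z ∇·v) φ` absorbs all passive-convection terms of
  the conservation-form equations; the strain law (not in conservation form)
  receives the compensating `−ε ∇·v` correction.
* **Quadrature / lumping** — vertex (Newton–Cotes) rule on every integral;
  the resulting diagonal mass matrix equals the row sums of the consistent
  P1 mass matrix, preserving monotonicity of the implicit stepping.
* **Time stepping** — backward Euler; a monolithic linear system over all
  ten nodal unknowns (the strain is carried with all four components
  ε₁₁, ε₁₂, ε₂₁, ε₂₂, which makes the discrete symmetry invariant checkable:
  symmetric data keeps `|ε₁₂ − ε₂₁|` at round-off) per Picard iteration,
  with every nonlinear coefficient frozen at the previous iterate.  Picard
  stops when the scaled max-norm update over all fields drops below 10⁻⁶
  (default; 25 iterations maximum).  The linear systems are equilibrated —
  columns scaled by per-field characteristic magnitudes (N̄ for cell
  densities, the Hill scale 10⁻⁸ g/cm³ for the signal, 0.1 for mechanics),
  then rows to unit max — and solved with a sparse direct factorization.
  Without the column scaling, round-off from the 10⁴-scale density rows
  leaks into the 10⁻¹⁴-scale signal concentration and masks its dynamics.
* **Moving mesh** — nodal displacement `u^{n+1} = u^n + Δt v`, evaluated
  inside the Picard loop with the current velocity iterate, so the converged
  step moves the mesh with the end-of-step velocity (the first iterate uses
  `v^n`).  This choice is what makes the published mesh-quality floor
  attainable: the initial velocity perturbation (0.5 cm/day) is damped to
  ~10⁻³ within the first implicit solve and never distorts the mesh.
  Mesh quality is monitored as `min|J|/max|J|`; below 0.5 the run halts with
  status `quality_halt` (remeshing is detected, not performed — the
  deep-instability scenario `δ_c = 2·10⁻⁴` is reproduced only up to its
  divergence).
* **Boundary conditions** — far-field Dirichlet (`N̄, 0, 0`, `v = 0`) on the
  outer boundary by row replacement; on the symmetry axes `v·n = 0` strongly
  and zero normal flux / zero tangential traction naturally.  No conditions
  on `ρ` and `ε` (their equations carry no spatial derivatives of their own
  unknowns).  Negative densities are reported as step diagnostics, never
  clipped; Hill denominators are domain-checked, not clamped.
* **Adaptive stepping** — `Δt = 10⁻²` day until half a day, then
  `Δt ← min{2, 1.1 Δt}`; convergence studies override with fixed `Δt = h²`.

## Scenarios

*Wound* (quarter-domain, `[0, 3.2]²` cm²): depleted square wound `[0, 1.2]²`
(2000 cells/cm³ fibroblasts, 10⁻⁸ g/cm³ signal, 0.01125 g/cm³ collagen)
ramped to equilibrium across a 0.8 cm transition.  The ramp is a product of
one-dimensional `sin²` profiles (1 inside, 0 beyond the transition, C¹ at
both junctions).  A product ramp rather than a distance-based one keeps the
initial data smooth along the diagonal; the published description fixes only
"sine" slopes, not the 2-D construction.

*Perturbation* (unit square): `N = N̄ + 10 sin(kπx)sin(kπy)` cells/cm³ and
`ρ = ρ̄ + 10⁻² sin(kπx)sin(kπy)` g/cm³; `M` and `c` are literal products of
two one-dimensional piecewise-linear bump splines with `2k+1` uniform knots
(boundary knots zero; interior knots alternating 3, 1 cells/cm³ and 2·10⁻⁷,
5·10⁻⁸ g/cm³).  The product construction means the effective peak
amplitudes are the squared knot values — e.g. the initial signal peak is
(2·10⁻⁷)² = 4·10⁻¹⁴ g/cm³, which is the order the published unstable run
starts from.  `v₁ = 0.5 sin(kπx)sin(kπy)` cm/day (the amplitude's units are
not stated in the source; cm/day is the only dimensionally consistent
choice), `v₂ = −v₁` to preserve the diagonal symmetry, strain zero.  All
generated fields satisfy the boundary conditions exactly and are
deterministic; the spline family and interior-value layout are one
admissible reading of an under-specified construction.

*Intervention reset*: clamp `c` and/or `M` to their healthy equilibria
everywhere mid-run, leaving every other field untouched — the numerical
analogue of abolishing growth-factor stimulation in a hypertrophic scar.

## What the scenarios do and do not emulate

The generators reproduce the study conditions exactly (amplitudes, wave
counts, domain and wound geometry, parameter values); they contain no
randomness.  They are synthetic perturbations of an idealized homogeneous
tissue: passing tests demonstrate internal consistency between the linear
analysis and the nonlinear solver — decay for `δ_c ≥ k_c/(a_c^II ρ̄)`,
slow signal-driven divergence below it — not agreement with clinical
contraction data, which involve heterogeneous tissue, 3-D geometry and
contact mechanics outside this model.

## Problem sizes

The long verification runs use: stable and mesh-quality runs at `h = 0.05`
on the unit square (841 nodes, ~195 adaptive steps to day 200); the
unstable-regime check at `h = 0.1` (same protocol; the signal growth at the
wound center is resolution-insensitive — 3.6 orders of magnitude between
day 13 and day 200 at both `h = 0.1` and `h = 0.05`).  The mesh-refinement
study in the test suite runs the wound protocol on a geometry-scaled domain
(`[0, 1.6]²`, wound side 0.6, transition 0.8, `h ∈ {0.2, 0.1, 0.05}`,
`Δt = h²`, day one), which preserves the published feature-to-mesh ratios
at a quarter of the published domain's cost; the full `[0, 3.2]²` protocol
is available through the same API (`convergence_study`) and the `converge`
CLI command.  Errors follow the discrete L2 norm `ε(z_h) = h √Σᵢ(z_h − z_ref)²`
over the material points that started at the coarsest lattice nodes, with
`h` the producing run's spacing, and the reference is the finest run.

## Known limitations

* Linear (Hookean) elasticity and the linear strain evolution law are valid
  for small effective strain; the special equilibrium (1/2, 0, 1/2) lies
  outside that validity region and is analyzed as a mathematical, not
  physical, statement.
* No remeshing: runs that would need it halt with a diagnostic.
* 2-D plane setting, isotropic single-type collagen, no angiogenesis or
  contact loading.
* The semi-discrete analysis assumes equal horizontal and vertical grid
  spacing.
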