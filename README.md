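# morphocontract

Stability analysis and moving-grid finite-element simulation of a
two-dimensional **biomorphoelastic model for post-burn skin contraction**.

Deep burns heal by contraction: growth factors released in the wound drive
fibroblasts to differentiate into myofibroblasts, which pull on the
regenerating collagen matrix.  If the signaling molecules decay too slowly,
myofibroblasts persist, collagen is over-produced, and the scar contracts
permanently (hypertrophy).  The model couples four biochemical fields —
fibroblasts *N*, myofibroblasts *M*, signaling molecules *c*, collagen *ρ* —
to a visco-elastic momentum balance for the displacement velocity **v** and
a morphoelastic evolution law for the effective strain **ε**, which makes
contraction permanent:

    Dε/Dt + ε skw(∇v) − skw(∇v) ε + (tr ε − 1) sym(∇v)
        = −ζ [N + η^II M] c / (1 + a_c^III c) · ε

The package is aimed at researchers in mechanobiological tissue modelling
who want to (i) evaluate the closed-form linear stability conditions of the
model, (ii) map which effective-strain equilibria are stable, (iii) verify
that a finite-difference semi-discretization inherits that stability, and
(iv) reproduce the predictions with a nonlinear moving-grid FEM simulator.

**The central result it operationalizes:** the healthy equilibrium
`(N̄, 0, 0, ρ̄)` is linearly stable if and only if the signaling-molecule
decay rate satisfies `δ_c ≥ k_c / (a_c^II ρ̄)`, together with
`q δ_N ≤ κ_F r_F N̄^{1+q}`; for wavelike perturbations the mechanical block
additionally requires the strain equilibrium to lie in a stable region of
`(ε̄₁₁, ε̄₂₂, ε̄₁₂)`-space that contains the origin for `|ε̄₁₂| ≤ 0.2`.

## Worked example

```python
from morphocontract import ModelParameters, StrainEquilibrium, derive_equilibrium
from morphocontract.stability import (WaveMode, chemical_conditions,
                                      mechanical_eigenvalues, stability_indicator)

p = ModelParameters.defaults()          # the published 33-parameter set
eq = derive_equilibrium(p)
print(f"rho_eq = {eq.rho_eq:.4f} g/cm^3")
for dc in (3e-4, 5e-4):
    cond = chemical_conditions(p.replace(delta_c=dc), WaveMode(0, 0))
    print(f"delta_c={dc:g}: conditions (N, M, c, rho) = {cond.round(4)}")
spec = mechanical_eigenvalues(p, StrainEquilibrium(0.5, 0.0, 0.5), WaveMode(1, 1))
print("mechanical eigenvalues:", spec.eigenvalues.real.round(0))
print("S at origin:", stability_indicator(p, StrainEquilibrium(0, 0, 0)))
```

prints

```
rho_eq = 0.1125 g/cm^3
delta_c=0.0003: conditions (N, M, c, rho) = [ 0.0085  0.06   -0.0625  0.0135]
delta_c=0.0005: conditions (N, M, c, rho) = [0.0085 0.06   0.1625 0.0135]
mechanical eigenvalues: [    0.     0.     0.  3622. 14487.]
S at origin: 1
```

Reading this: the collagen equilibrium is √(k_ρ/δ_ρ) = 0.1125 g/cm³.  The
four numbers per row are the closed-form eigenvalues of the biochemical
block at the constant mode — all must be nonnegative for stability.  At
δ_c = 3·10⁻⁴ cm⁶/(cells·g·day) the signaling-molecule eigenvalue is
−0.0625/day: perturbations of the signal *grow* at that rate, and the
long-time simulation develops a persistent myofibroblast/collagen focus
(the model's picture of a hypertrophic scar).  At δ_c = 5·10⁻⁴ all four are
positive and every perturbation decays.  At the special strain equilibrium
(½, 0, ½) the mechanical block has the zero eigenvalue with multiplicity
three plus two real positive viscous rates (1/day); `S = 1` marks strain
equilibria whose mechanical spectrum stays in the right half-plane for all
wave pairs up to (100, 100).

The nonlinear simulator confirms the dichotomy from the shell:

```bash
morphocontract simulate --scenario perturbation --delta-c 5e-4 --k 1 --T 10 --h 0.1 --out out/
morphocontract stability-map --strain-step 0.1 --e12-levels -1,0 --mode-range 30,30 --out map/
morphocontract converge --h 0.4,0.2 --out conv/
```

The first writes per-step traces (`timeseries.csv`), a run log with mesh
quality and Picard counts, and VTK snapshots; the velocity sup-norm decays
from 0.5 cm/day to below 10⁻⁴ cm/day within ten simulated days.

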