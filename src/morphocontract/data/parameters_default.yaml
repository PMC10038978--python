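# Default parameter set for the 2-D biomorphoelastic post-burn contraction model.
# Units: cm, day, g, cells, N.  Symbols follow the model's standard notation.
D_F: 1.0e-7        # cm^5/(cells day)   (myo)fibroblast random-walk diffusion
chi_F: 2.0e-3      # cm^5/(g day)       chemotactic sensitivity
D_c: 2.88e-3       # cm^2/day           signaling-molecule diffusion
r_F: 9.24e-1       # cm^{3q}/(cells^q day)  fibroblast division rate
r_F_max: 2.0       # -                  max division-rate enhancement
a_c_I: 1.0e-8      # g/cm^3             half-max enhancement concentration (division)
kappa_F: 1.0e-6    # cm^3/cells         crowding reduction of division
q: -4.151e-1       # -                  fixed division exponent (NC)
k_F: 1.08e7        # cm^3/(g day)       differentiation rate constant
delta_N: 2.0e-2    # 1/day              fibroblast apoptosis rate
delta_M: 6.0e-2    # 1/day              myofibroblast apoptosis rate
k_c: 4.0e-13       # g/(cells day)      max net secretion of signaling molecules
eta_I: 2.0         # -                  myo/fibro secretion ratio (c and rho)
eta_II: 5.0e-1     # -                  myo/fibro MMP-secretion ratio
a_c_II: 1.0e-8     # cm^3/g             half-max secretion concentration (c)
a_c_III: 2.0e8     # g/cm^3             MMP-secretion inhibition constant
a_c_IV: 1.0e-9     # g/cm^3             half-max enhancement concentration (rho)
delta_c: 5.0e-4    # cm^6/(cells g day) signaling-molecule proteolytic decay
k_rho: 7.6e-8      # g/(cells day)      collagen secretion rate (NC)
k_rho_max: 10.0    # -                  max secretion-rate enhancement
delta_rho: 6.0e-6  # cm^6/(cells g day) collagen degradation rate
N_bar: 1.0e4       # cells/cm^3         fibroblast equilibrium density
M_bar: 0.0         # cells/cm^3         myofibroblast equilibrium density
c_bar: 0.0         # g/cm^3             signaling-molecule equilibrium
rho_bar: 1.125e-1  # g/cm^3             collagen equilibrium density
rho_t: 1.09        # g/cm^3             total dermal mass density
mu_1: 1.0e2        # (N day)/cm^2       shear viscosity
mu_2: 1.0e2        # (N day)/cm^2       bulk viscosity
nu: 4.9e-1         # -                  Poisson's ratio
E: 3.2e1           # N/((g cm)^0.5)     stiffness (Young's modulus = E sqrt(rho))
xi: 4.4e-2         # (N g)/(cells cm^2) myofibroblast traction per unit density
R: 9.95e-1         # g/cm^3             traction saturation constant
zeta: 4.0e2        # cm^6/(cells g day) rate of morphoelastic change
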