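import numpy as np
import pytest

from morphocontract import StrainEquilibrium
from morphocontract.stability import (
    GridSpec,
    WaveMode,
    assemble_mode_matrix,
    assemble_semidiscrete_matrix,
    chemical_conditions,
    eigenvalue_gap_convergence,
    integrator_amplification,
    semidiscrete_conditions,
    stability_verdict,
)

ORIGIN = StrainEquilibrium(0.0, 0.0, 0.0)
STRAIN = StrainEquilibrium(0.1, -0.2, 0.3)


class TestAssembly:
    def test_entrywise_limit_recovers_continuous_matrix(self, table2):
        mode = WaveMode(1, 2)
        cont = assemble_mode_matrix(table2, STRAIN, mode).matrix
        for h, tol in ((1e-2, 5e-3), (1e-3, 5e-5), (1e-4, 5e-7)):
            semi = assemble_semidiscrete_matrix(
                table2, STRAIN, mode, GridSpec.from_spacing(h)
            ).matrix
            scale = np.abs(cont).max()
            assert np.abs(semi - cont).max() <= tol * scale

    def test_signaling_diagonal_published_value(self, table2):
        semi = assemble_semidiscrete_matrix(
            table2, ORIGIN, WaveMode(1, 1), GridSpec.from_spacing(0.1)
        ).matrix
        # (4 D_c / h^2) 2 sin^2(0.1 pi) + 0.1625
        expected = 4 * table2.D_c / 0.01 * 2 * np.sin(0.1 * np.pi) ** 2 + 0.1625
        assert semi[0, 0].real == pytest.approx(expected, rel=1e-12)
        assert expected == pytest.approx(0.3825, abs=5e-5)

    def test_aliased_mode_reduces_to_reaction_part(self, table2):
        # l h integer: all sine factors vanish
        grid = GridSpec.from_spacing(0.1)
        semi = assemble_semidiscrete_matrix(table2, STRAIN, WaveMode(10, 20), grid)
        react = assemble_mode_matrix(table2, STRAIN, WaveMode(0, 0))
        assert np.allclose(semi.matrix, react.matrix)

    def test_entrywise_difference_is_second_order(self, table2):
        mode = WaveMode(1, 2)
        cont = assemble_mode_matrix(table2, STRAIN, mode).matrix
        hs = np.array([1 / 16, 1 / 32, 1 / 64, 1 / 128])
        diffs = np.stack(
            [
                np.abs(
                    assemble_semidiscrete_matrix(
                        table2, STRAIN, mode, GridSpec.from_spacing(h)
                    ).matrix
                    - cont
                )
                for h in hs
            ]
        )
        mask = diffs[0] > 1e-12 * np.abs(cont).max()
        assert mask.any()
        for i, j in zip(*np.nonzero(mask)):
            slope = np.polyfit(np.log(hs), np.log(diffs[:, i, j]), 1)[0]
            assert slope == pytest.approx(2.0, abs=0.05)


class TestConditions:
    def test_mechanical_boundary_at_zero_viscosity(self, table2):
        p = table2.replace(mu_1=0.0, mu_2=0.0)
        values = semidiscrete_conditions(p, WaveMode(3, 4), GridSpec.from_spacing(0.1))
        assert values[4] == pytest.approx(0.0, abs=1e-15)

    def test_collagen_condition_grid_independent(self, table2):
        for h in (0.5, 0.1, 0.02):
            for mode in (WaveMode(0, 0), WaveMode(1, 1), WaveMode(7, 3)):
                values = semidiscrete_conditions(table2, mode, GridSpec.from_spacing(h))
                assert values[3] == pytest.approx(0.0135, rel=1e-12)

    def test_mechanical_condition_nonnegative_sweep(self, table2, rng):
        # brute-force lattice of (l, p, h) plus random viscosities
        for _ in range(25):
            p = table2.replace(mu_1=rng.uniform(0, 300), mu_2=rng.uniform(0, 300))
            for h in (0.25, 0.1, 0.05):
                for l in range(0, 8, 3):
                    for q in range(0, 8, 3):
                        values = semidiscrete_conditions(
                            p, WaveMode(l, q), GridSpec.from_spacing(h)
                        )
                        assert values[4] >= -1e-9 * max(1.0, abs(values[4]))

    def test_continuous_stability_implies_semidiscrete(self, table2, rng):
        # random admissible parameter draws satisfying the closed-form
        # stability conditions; every semi-discrete condition value >= 0
        for _ in range(20):
            p = table2.replace(
                delta_c=rng.uniform(4e-4, 1e-3),
                mu_1=rng.uniform(0, 300),
                mu_2=rng.uniform(0, 300),
                D_F=rng.uniform(1e-8, 1e-6),
                D_c=rng.uniform(1e-4, 1e-2),
            )
            assert np.all(chemical_conditions(p, WaveMode(0, 0)) >= 0)
            for h in (0.2, 0.1):
                for l in (0, 1, 3, 10):
                    for q in (0, 2, 5):
                        values = semidiscrete_conditions(
                            p, WaveMode(l, q), GridSpec.from_spacing(h)
                        )
                        assert np.all(values >= -1e-12)


class TestEigenvalueGaps:
    def test_zero_mode_has_zero_gaps(self, table2):
        with pytest.raises(ValueError):
            eigenvalue_gap_convergence(table2, WaveMode(0, 0), [0.1, 0.05])
        rep = eigenvalue_gap_convergence(table2, WaveMode(0, 0), [0.1, 0.05, 0.025])
        assert all(np.allclose(g, 0.0) for g in rep.gap_values.values())
        assert all(np.isnan(s) for s in rep.fitted_slopes.values())

    def test_signaling_gap_slope_second_order(self, table2):
        rep = eigenvalue_gap_convergence(
            table2, WaveMode(1, 1), [0.1, 0.05, 0.025, 0.0125]
        )
        assert rep.fitted_slopes["c"] == pytest.approx(2.0, abs=0.02)
        assert rep.fitted_slopes["N"] == pytest.approx(2.0, abs=0.02)
        assert np.isnan(rep.fitted_slopes["rho"])  # no diffusion, no gap

    def test_leading_gap_coefficient_matches_taylor(self, table2):
        # gap ~ D_c (8 pi^4 / 3) h^2 at mode (1,1)
        rep = eigenvalue_gap_convergence(table2, WaveMode(1, 1), [0.1, 0.05, 0.025])
        taylor = table2.D_c * (8 * np.pi**4 / 3) * 0.1**2
        assert taylor == pytest.approx(0.00748, abs=2e-5)
        assert rep.gap_values["c"][0] == pytest.approx(taylor, rel=0.02)


class TestIntegratorAmplification:
    def test_neutral_mode(self):
        assert integrator_amplification(0.0, 1.0, "euler_backward") == 1.0
        assert integrator_amplification(0.0, 1.0, "trapezoid") == 1.0

    def test_euler_backward_halves_unit_rate(self):
        assert integrator_amplification(1.0, 1.0, "euler_backward") == pytest.approx(0.5)

    @pytest.mark.parametrize("scheme", ["euler_backward", "trapezoid"])
    def test_a_stability(self, scheme, rng):
        for _ in range(200):
            lam = complex(rng.uniform(0, 1e4), rng.uniform(-1e4, 1e4))
            dt = 10.0 ** rng.uniform(-3, 1)
            assert integrator_amplification(lam, dt, scheme) <= 1.0 + 1e-12

    def test_stable_chemical_rates_are_damped(self, table2):
        # Corollary hook: every stable chemical eigenvalue is damped by both
        # rules for any step size
        v = stability_verdict(table2, ORIGIN, WaveMode(2, 2))
        for lam in v.chemical_condition_values:
            for dt in (0.01, 0.5, 2.0, 100.0):
                assert integrator_amplification(lam, dt, "euler_backward") <= 1.0
                assert integrator_amplification(lam, dt, "trapezoid") <= 1.0

    def test_errors(self):
        with pytest.raises(ValueError):
            integrator_amplification(1.0, 0.0, "euler_backward")
        with pytest.raises(ZeroDivisionError):
            integrator_amplification(-1.0, 1.0, "euler_backward")
        with pytest.raises(ValueError):
            integrator_amplification(1.0, 1.0, "runge_kutta")
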