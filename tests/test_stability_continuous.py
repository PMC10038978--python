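import numpy as np
import pytest

from morphocontract import StrainEquilibrium
from morphocontract.stability import (
    WaveMode,
    assemble_mode_matrix,
    chemical_conditions,
    gershgorin_special_equilibrium,
    mechanical_block,
    mechanical_eigenvalues,
    stability_indicator,
    stability_map,
    stability_verdict,
)

ORIGIN = StrainEquilibrium(0.0, 0.0, 0.0)
SPECIAL = StrainEquilibrium(0.5, 0.0, 0.5)
# verified unstable triples (high-precision charpoly oracle)
UNSTABLE = [
    StrainEquilibrium(0.9, -1.0, 0.9),
    StrainEquilibrium(1.0, 1.0, 1.0),
    StrainEquilibrium(-0.2, -1.0, -0.2),
]


class TestModeMatrix:
    def test_signal_decay_diagonal_entry(self, table2):
        A = assemble_mode_matrix(table2, ORIGIN, WaveMode(0, 0)).matrix
        # N_bar (delta_c rho_bar - k_c / a_c_II)
        assert A[0, 0].real == pytest.approx(0.1625, rel=1e-12)

    def test_collagen_diagonal_entry(self, table2):
        A = assemble_mode_matrix(table2, ORIGIN, WaveMode(0, 0)).matrix
        assert A[3, 3].real == pytest.approx(0.0135, rel=1e-12)

    def test_sparsity_pattern(self, table2):
        A = assemble_mode_matrix(table2, StrainEquilibrium(0.1, -0.2, 0.3),
                                 WaveMode(2, 3)).matrix
        # biochemical rows never see the mechanics
        assert np.allclose(A[:4, 4:], 0.0)
        # chemical block lower-triangular
        assert np.allclose(np.triu(A[:4, :4], k=1), 0.0)
        # strain rows couple only to (c, v1, v2)
        assert np.allclose(A[6:, 1:4], 0.0)
        assert np.allclose(A[6:, 6:], 0.0)

    def test_strain_velocity_coupling_vanishes_at_special_equilibrium(self, table2):
        A = assemble_mode_matrix(table2, SPECIAL, WaveMode(3, 7)).matrix
        assert np.allclose(A[6:, 4:6], 0.0)

    def test_chemical_diagonal_matches_condition_values(self, table2):
        mode = WaveMode(2, 5)
        A = assemble_mode_matrix(table2, ORIGIN, mode).matrix
        cond = chemical_conditions(table2, mode)
        diag = np.array([A[2, 2], A[1, 1], A[0, 0], A[3, 3]]).real
        assert np.allclose(cond, diag)


class TestChemicalConditions:
    def test_constant_mode_values(self, table2):
        cond = chemical_conditions(table2, WaveMode(0, 0))
        assert cond[0] == pytest.approx(0.0085, abs=5e-5)  # fibroblast
        assert cond[1] == pytest.approx(table2.delta_M)
        assert cond[2] == pytest.approx(0.1625, rel=1e-12)  # signaling
        assert cond[3] == pytest.approx(0.0135, rel=1e-12)  # collagen

    def test_decay_threshold_classification(self, table2):
        # only delta_c = 5e-4 satisfies delta_c rho_bar >= k_c / a_c_II
        signs = {}
        for delta_c in (2e-4, 3e-4, 5e-4):
            p = table2.replace(delta_c=delta_c)
            signs[delta_c] = chemical_conditions(p, WaveMode(0, 0))[2] >= 0
        assert signs == {2e-4: False, 3e-4: False, 5e-4: True}
        p3 = table2.replace(delta_c=3e-4)
        assert chemical_conditions(p3, WaveMode(0, 0))[2] == pytest.approx(
            -0.0625, rel=1e-12
        )

    @pytest.mark.parametrize("delta_c", [2e-4, 5e-4])
    def test_nondecreasing_in_wavenumber(self, table2, delta_c):
        # diffusion only adds nonnegative terms: stability at (0,0) implies all
        p = table2.replace(delta_c=delta_c)
        modes = [WaveMode(0, 0), WaveMode(1, 0), WaveMode(1, 1), WaveMode(2, 3),
                 WaveMode(10, 10), WaveMode(100, 7)]
        values = np.array([chemical_conditions(p, m) for m in modes])
        order = np.argsort([m.l**2 + m.p**2 for m in modes])
        assert np.all(np.diff(values[order], axis=0) >= -1e-12)


class TestMechanicalSpectrum:
    @pytest.mark.parametrize("mode", [WaveMode(1, 1), WaveMode(1, 0),
                                      WaveMode(4, 9), WaveMode(50, 50)])
    def test_zero_eigenvalue_multiplicity_three_at_special(self, table2, mode):
        spec = mechanical_eigenvalues(table2, SPECIAL, mode)
        block = mechanical_block(table2, SPECIAL,
                                 np.asarray(mode.l), np.asarray(mode.p))
        lam = np.linalg.eigvals(block)
        tol = 1e-9 * np.abs(block).max()
        assert np.sum(np.abs(lam) < tol) == 3
        assert spec.closed_form
        nonzero = spec.eigenvalues[np.abs(spec.eigenvalues) >= tol]
        assert nonzero.size == 2
        assert np.all(np.abs(nonzero.imag) < tol)  # real-valued
        assert np.all(nonzero.real >= 0.0)

    def test_decoupled_velocity_block_closed_form(self, table2):
        # mode (1,0): A56 = 0, eigenvalues are the two viscous diagonal rates
        spec = mechanical_eigenvalues(table2, SPECIAL, WaveMode(1, 0))
        w2 = (2 * np.pi) ** 2
        expected = sorted(
            [w2 * (table2.mu_1 + table2.mu_2) / table2.rho_t,
             w2 * table2.mu_1 / (2 * table2.rho_t)]
        )
        got = sorted(spec.eigenvalues.real[-2:])
        assert got == pytest.approx(expected, rel=1e-12)
        assert got == pytest.approx([1810.94, 7243.75], rel=1e-4)

    def test_constant_mode_spectrum_is_zero(self, table2):
        spec = mechanical_eigenvalues(table2, SPECIAL, WaveMode(0, 0))
        assert np.allclose(spec.eigenvalues, 0.0)

    def test_discriminant_nonnegative_random_viscosities(self, table2, rng):
        for _ in range(50):
            p = table2.replace(mu_1=rng.uniform(0, 500), mu_2=rng.uniform(0, 500))
            mode = WaveMode(int(rng.integers(0, 20)), int(rng.integers(0, 20)))
            spec = mechanical_eigenvalues(p, SPECIAL, mode)
            assert spec.discriminant >= -1e-9 * max(1.0, abs(spec.discriminant))

    def test_quadratic_reduction_identity_random_viscosities(self, table2, rng):
        # (1/2 (wl^4 + wp^4) + wl^2 wp^2)(mu1^2 + mu1 mu2) >= 0 reformulation:
        # A55 A66 - A56^2 >= 0 for all mu1, mu2 >= 0
        for _ in range(50):
            p = table2.replace(mu_1=rng.uniform(0, 500), mu_2=rng.uniform(0, 500))
            l, pp = int(rng.integers(0, 30)), int(rng.integers(0, 30))
            b = mechanical_block(p, SPECIAL, np.asarray(l), np.asarray(pp))
            det2 = b[0, 0].real * b[1, 1].real - b[0, 1].real ** 2
            assert det2 >= -1e-6 * max(1.0, abs(det2))


class TestStabilityIndicator:
    def test_stable_at_origin(self, table2):
        assert stability_indicator(table2, ORIGIN, 30, 30) == 1

    def test_stable_at_special_equilibrium(self, table2):
        assert stability_indicator(table2, SPECIAL, 30, 30) == 1

    @pytest.mark.parametrize("strain", UNSTABLE)
    def test_unstable_triples(self, table2, strain):
        assert stability_indicator(table2, strain, 30, 30) == 0

    def test_agrees_with_full_matrix_eigensolve(self, table2, rng):
        # oracle: brute-force eigendecomposition of the 9x9 matrix restricted
        # to its mechanical block, worst real part over a small mode sweep
        for _ in range(10):
            strain = StrainEquilibrium(*rng.uniform(-1, 1, size=3))
            worst = 0.0
            norm = 0.0
            for l in range(1, 9):
                for p in range(1, 9):
                    A = assemble_mode_matrix(table2, strain, WaveMode(l, p)).matrix
                    block = A[4:, 4:]
                    worst = min(worst, np.linalg.eigvals(block).real.min())
                    norm = max(norm, np.abs(block).max())
            oracle = int(worst >= -1e-12 * max(norm, 1.0))
            assert stability_indicator(table2, strain, 8, 8) == oracle

    def test_verdict_combines_chemical_and_mechanical(self, table2):
        v = stability_verdict(table2, ORIGIN, WaveMode(1, 1))
        assert v.stable
        v_bad = stability_verdict(table2.replace(delta_c=2e-4), ORIGIN, WaveMode(0, 0))
        assert not v_bad.stable


@pytest.fixture(scope="module")
def coarse_map(table2):
    grid = np.linspace(-1.0, 1.0, 11)
    return stability_map(table2, grid, grid, [-1.0, -0.5, 0.0],
                         mode_range=(12, 12))


class TestStabilityMap:
    def test_symmetric_under_normal_strain_exchange(self, coarse_map):
        for k in range(coarse_map.e12_levels.size):
            assert np.array_equal(coarse_map.S[k], coarse_map.S[k].T)

    def test_stable_area_nondecreasing_in_e12(self, coarse_map):
        areas = [coarse_map.stable_area(k) for k in range(3)]
        assert areas == sorted(areas)

    def test_origin_in_contiguous_stable_region_at_zero_shear(self, coarse_map):
        S = coarse_map.S[2]  # e12 = 0
        mid = S.shape[0] // 2
        assert S[mid, mid] == 1
        # flood fill from the origin; the stable set must be one component
        from scipy import ndimage

        labels, nlab = ndimage.label(S)
        assert labels[mid, mid] > 0
        assert (labels == labels[mid, mid]).sum() == S.sum()


class TestGershgorin:
    def test_special_equilibrium_value(self):
        eq = gershgorin_special_equilibrium()
        assert eq.as_tuple() == pytest.approx((0.5, 0.0, 0.5), abs=1e-12)

    @pytest.mark.parametrize("alpha,beta", [(1, 0), (0, 1), (1, 1), (3, 5), (-2, 7)])
    def test_residual_zero_for_any_wave_pair(self, alpha, beta):
        e11, e12, e22 = gershgorin_special_equilibrium().as_tuple()
        a, b = abs(alpha), abs(beta)
        assert a * (e11 + e12 + e22 - 1.0) - b * e12 == pytest.approx(0.0, abs=1e-12)
        assert a * (e11 - 0.5) + b * (e22 - 0.5) == pytest.approx(0.0, abs=1e-12)
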