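"""Constitutive verification: closed forms, stress-energy consistency,
objectivity, and the incompressible-penalty limit."""

import math

import numpy as np
import pytest
from scipy.optimize import brentq
from scipy.spatial.transform import Rotation

from aclfem.errors import (
    InvertedConfigurationError,
    ValidationError,
)
from aclfem.materials import (
    DeformationState,
    FiberTerm,
    LinearElasticParams,
    NeoHookeanParams,
    cauchy_stress_hyper,
    fiber_stretch,
    material_tangent,
    pk2_stress,
    small_strain_stress,
    strain_energy_density,
)

MATRIX = NeoHookeanParams()          # C1 = 1.95 MPa, D = 0.00683 1/MPa


def random_F(rng, scale=0.2):
    while True:
        F = np.eye(3) + scale * rng.standard_normal((3, 3))
        if 0.8 <= np.linalg.det(F) <= 1.3:
            return F


class TestStrainEnergy:
    def test_zero_at_reference(self):
        assert strain_energy_density(np.eye(3), MATRIX) == 0.0

    def test_pure_dilation_volumetric_term(self):
        # J = 1.02^3, isochoric part vanishes
        F = 1.02 * np.eye(3)
        expected = math.log(1.02**3) ** 2 / (2 * 0.00683)
        assert strain_energy_density(F, MATRIX) == pytest.approx(
            expected, rel=1e-12
        )

    def test_isochoric_uniaxial(self):
        lam = 1.1
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        I1bar = lam**2 + 2.0 / lam
        assert strain_energy_density(F, MATRIX) == pytest.approx(
            1.95 * (I1bar - 3.0), rel=1e-12
        )

    def test_inverted_configuration_rejected(self):
        with pytest.raises(InvertedConfigurationError):
            strain_energy_density(-np.eye(3), MATRIX)

    def test_squared_invariant_variant_is_stiffer(self):
        lam = 1.2
        F = np.diag([lam, lam**-0.5, lam**-0.5])
        lit = NeoHookeanParams(squared_invariant=True)
        assert strain_energy_density(F, lit) > strain_energy_density(
            F, MATRIX
        )

    def test_k_times_D_is_one(self):
        assert MATRIX.k * MATRIX.D == pytest.approx(1.0, abs=1e-12)


class TestCauchyStress:
    def test_zero_at_reference(self):
        assert np.allclose(cauchy_stress_hyper(np.eye(3), MATRIX), 0.0)

    def test_symmetry(self):
        rng = np.random.default_rng(0)
        for _ in range(10):
            s = cauchy_stress_hyper(random_F(rng), MATRIX)
            assert np.max(np.abs(s - s.T)) < 1e-12

    def test_incompressible_uniaxial_closed_form(self):
        """Penalty k = 1e4 MPa reproduces sigma = 2 C1 (lam^2 - 1/lam)
        within 2%."""
        stiff = NeoHookeanParams(C1=1.95, D=1e-4)
        lam = 1.1

        def lateral(m):
            return cauchy_stress_hyper(np.diag([lam, m, m]), stiff)[1, 1]

        m = brentq(lateral, 0.5, 1.2)
        axial = cauchy_stress_hyper(np.diag([lam, m, m]), stiff)[0, 0]
        closed = 2 * 1.95 * (lam**2 - 1.0 / lam)   # ~1.174 MPa
        assert closed == pytest.approx(1.1735, abs=1e-3)
        assert axial == pytest.approx(closed, rel=0.02)

    def test_matches_energy_gradient_on_random_states(self):
        """Analytic stress vs central differences of Psi on 100 states."""
        rng = np.random.default_rng(42)
        h = 1e-6
        for _ in range(100):
            F = random_F(rng)
            sig = cauchy_stress_hyper(F, MATRIX)
            P = np.zeros((3, 3))
            for i in range(3):
                for j in range(3):
                    Fp, Fm = F.copy(), F.copy()
                    Fp[i, j] += h
                    Fm[i, j] -= h
                    P[i, j] = (
                        strain_energy_density(Fp, MATRIX)
                        - strain_energy_density(Fm, MATRIX)
                    ) / (2 * h)
            sig_fd = (P @ F.T) / np.linalg.det(F)
            scale = max(1.0, np.abs(sig).max())
            assert np.max(np.abs(sig_fd - sig)) / scale < 1e-6

    def test_objectivity(self):
        rng = np.random.default_rng(7)
        for _ in range(20):
            F = random_F(rng)
            Q = Rotation.random(random_state=rng).as_matrix()
            assert strain_energy_density(Q @ F, MATRIX) == pytest.approx(
                strain_energy_density(F, MATRIX), abs=1e-10, rel=1e-10
            )

    def test_material_tangent_consistent_with_stress(self):
        rng = np.random.default_rng(5)
        F = random_F(rng)
        C = F.T @ F
        CC = material_tangent(C[None], MATRIX)[0]
        h = 1e-6
        for (m, n) in [(0, 0), (0, 1), (1, 2)]:
            dC = np.zeros((3, 3))
            dC[m, n] += h
            dC[n, m] += h
            fd = (pk2_stress(C + dC, MATRIX)
                  - pk2_stress(C - dC, MATRIX)) / (2 * h)
            assert np.allclose(CC[:, :, m, n], fd, rtol=1e-4, atol=1e-6)


class TestLinearElastic:
    BONE = LinearElasticParams()     # E = 389 MPa, nu = 0.3

    def test_zero_strain_zero_stress(self):
        assert np.allclose(small_strain_stress(np.zeros((3, 3)), self.BONE),
                           0.0)

    def test_uniaxial_stress_1000_microstrain(self):
        """A uniaxial *stress* state with 1000 ue axial strain carries
        sigma = E * eps = 0.389 MPa."""
        eps_ax = 1e-3
        eps_lat = -self.BONE.nu * eps_ax
        eps = np.diag([eps_ax, eps_lat, eps_lat])
        sig = small_strain_stress(eps, self.BONE)
        assert sig[0, 0] == pytest.approx(0.389, rel=1e-9)
        assert sig[1, 1] == pytest.approx(0.0, abs=1e-12)

    def test_pure_shear(self):
        gamma = 1e-3
        eps = np.zeros((3, 3))
        eps[0, 1] = eps[1, 0] = gamma / 2
        G = 389.0 / (2 * 1.3)
        sig = small_strain_stress(eps, self.BONE)
        assert sig[0, 1] == pytest.approx(G * gamma, rel=1e-9)

    def test_linearity(self):
        rng = np.random.default_rng(1)
        e = rng.standard_normal((3, 3)) * 1e-3
        e = 0.5 * (e + e.T)
        s1 = small_strain_stress(e, self.BONE)
        s2 = small_strain_stress(2 * e, self.BONE)
        assert np.allclose(s2, 2 * s1)

    def test_asymmetric_strain_rejected(self):
        eps = np.zeros((3, 3))
        eps[0, 1] = 1e-3
        with pytest.raises(ValidationError):
            small_strain_stress(eps, self.BONE)

    def test_parameter_domains(self):
        with pytest.raises(ValidationError):
            LinearElasticParams(E=-1.0)
        with pytest.raises(ValidationError):
            LinearElasticParams(nu=0.6)


class TestFiberStretch:
    def test_identity(self):
        assert fiber_stretch(np.eye(3), (0, 0, 1)) == pytest.approx(1.0)

    def test_axis_aligned(self):
        F = np.diag([1.2, 1.0, 1.0])
        assert fiber_stretch(F, (1, 0, 0)) == pytest.approx(1.2)

    def test_rotation_invariance(self):
        rng = np.random.default_rng(11)
        for _ in range(50):
            Q = Rotation.random(random_state=rng).as_matrix()
            assert fiber_stretch(Q, (0, 0, 1)) == pytest.approx(
                1.0, abs=1e-12
            )

    def test_non_unit_direction_rejected(self):
        with pytest.raises(ValidationError):
            fiber_stretch(np.eye(3), (0, 0, 2))

    def test_fiber_term_no_compression_resistance(self):
        ft = FiberTerm(enabled=True, c3=1.0, c4=30.0, lam_star=1.08)
        assert ft.energy(0.95) == 0.0
        assert ft.dpsi_dlam(0.95) == 0.0
        assert ft.energy(1.05) > 0.0
        # linear region continues with the toe-end slope
        assert ft.dpsi_dlam(1.5) == pytest.approx(ft.dpsi_dlam(1.08),
                                                  rel=1e-9)

    def test_deformation_state_invariants(self):
        st = DeformationState.from_F(np.diag([1.1, 1.0, 1.0]))
        assert st.J == pytest.approx(1.1)
        assert st.I1bar >= 3.0
        rngQ = Rotation.from_euler("xyz", [10, 20, 30], degrees=True)
        st2 = DeformationState.from_F(rngQ.as_matrix())
        assert st2.I1bar == pytest.approx(3.0, abs=1e-12)
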