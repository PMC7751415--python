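"""Coil-field, magnetization and force law tests against independent oracles."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from magsteer import magnetics
from magsteer.magnetics import (MU0, KB, CoilSpec, ParticleSpec, coil_field,
                                drift_velocity, langevin,
                                magnetic_force, magnetization,
                                moment_coefficient, total_field,
                                total_field_arrays)


def on_axis_closed_form(coil: CoilSpec, current: float, z: float) -> float:
    """Independent oracle: H_z = N I a^2 / (2 (a^2 + z^2)^{3/2})."""
    a = coil.radius
    return coil.turns * current * a**2 / (2.0 * (a**2 + z**2) ** 1.5)


class TestCoilField:
    def test_center_magnitude(self, coil):
        # at the loop center |H| = N I / (2 a), along the axis
        s = coil_field(coil, 1.0, [0.0, 0.0, 0.0])
        assert s.H[2] == pytest.approx(coil.turns * 1.0 / (2 * coil.radius), rel=1e-12)
        assert abs(s.H[0]) < 1e-12 and abs(s.H[1]) < 1e-12

    def test_on_axis_oracle(self, coil):
        zs = np.linspace(-0.2, 0.2, 20)
        for z in zs:
            s = coil_field(coil, 2.5, [0.0, 0.0, z])
            assert s.H[2] == pytest.approx(on_axis_closed_form(coil, 2.5, z),
                                           rel=1e-8)

    def test_zero_current(self, coil):
        s = coil_field(coil, 0.0, [0.01, 0.02, 0.03])
        assert np.all(s.H == 0.0) and np.all(s.jacobian == 0.0)

    def test_linearity_in_current(self, coil):
        p = [0.02, -0.01, 0.04]
        s1 = coil_field(coil, 1.0, p)
        s3 = coil_field(coil, 3.0, p)
        np.testing.assert_allclose(s3.H, 3.0 * s1.H, rtol=1e-13)
        np.testing.assert_allclose(s3.jacobian, 3.0 * s1.jacobian, rtol=1e-13)

    def test_b_is_mu0_h(self, coil):
        s = coil_field(coil, 1.0, [0.02, 0.0, 0.03])
        np.testing.assert_allclose(s.B, MU0 * s.H, rtol=0, atol=0)

    def test_jacobian_matches_finite_differences(self, coil, rng):
        pts = rng.uniform(-0.08, 0.08, size=(10, 3))
        # keep clear of the filament
        pts = pts[np.abs(np.hypot(np.hypot(pts[:, 0], pts[:, 1]) - coil.radius,
                                  pts[:, 2])) > 5e-3]
        h = 1e-7
        for p in pts:
            s = coil_field(coil, 1.0, p)
            fd = np.empty((3, 3))
            for j in range(3):
                dp = np.zeros(3)
                dp[j] = h
                fd[:, j] = (coil_field(coil, 1.0, p + dp).H
                            - coil_field(coil, 1.0, p - dp).H) / (2 * h)
            scale = np.abs(fd).max()
            np.testing.assert_allclose(s.jacobian, fd, atol=1e-5 * scale)

    def test_on_axis_jacobian_is_divergence_free_limit(self, coil):
        s = coil_field(coil, 1.0, [0.0, 0.0, 0.07])
        J = s.jacobian
        assert np.trace(J) == pytest.approx(0.0, abs=1e-9 * np.abs(J).max())
        assert J[0, 0] == pytest.approx(-J[2, 2] / 2, rel=1e-12)

    def test_filament_singularity_raises(self, coil):
        with pytest.raises(ValueError, match="filament"):
            coil_field(coil, 1.0, [coil.radius, 0.0, 0.0])

    def test_nonfinite_input_raises(self, coil):
        with pytest.raises(ValueError):
            coil_field(coil, np.nan, [0.0, 0.0, 0.01])


class TestSuperposition:
    def _pair(self):
        # coaxial Helmholtz-like pair, 0.2 m apart, common +z axis
        c1 = CoilSpec(center=[0, 0, -0.1], axis=[0, 0, 1.0], radius=0.05, turns=100)
        c2 = CoilSpec(center=[0, 0, 0.1], axis=[0, 0, 1.0], radius=0.05, turns=100)
        return [c1, c2]

    def test_midpoint_symmetry(self):
        coils = self._pair()
        # equal currents: transverse components cancel at the midpoint and
        # the field magnitude is stationary there (grad(H^2) = 0)
        samples = total_field(coils, [1.0, 1.0], [[0.0, 0.0, 0.0]])
        H, J = samples[0].H, samples[0].jacobian
        assert abs(H[0]) < 1e-12 and abs(H[1]) < 1e-12
        assert H[2] > 0.0
        grad_h2 = 2.0 * J.T @ H
        assert np.linalg.norm(grad_h2) <= 1e-9 * np.linalg.norm(H) ** 2

    def test_zero_currents(self):
        coils = self._pair()
        H, J = total_field_arrays(coils, [0.0, 0.0], [[0.01, 0.0, 0.02]])
        assert np.all(H == 0) and np.all(J == 0)

    def test_single_active_coil_matches_coil_field(self):
        coils = self._pair()
        p = [0.01, -0.02, 0.03]
        sample = total_field(coils, [1.0, 0.0], [p])[0]
        alone = coil_field(coils[0], 1.0, p)
        np.testing.assert_array_equal(sample.H, alone.H)
        np.testing.assert_array_equal(sample.jacobian, alone.jacobian)

    def test_shape_mismatch_raises(self):
        with pytest.raises(ValueError):
            total_field(self._pair(), [1.0], [[0, 0, 0]])

    def test_scaling_all_currents(self):
        coils = self._pair()
        pts = [[0.01, 0.02, 0.0], [0.0, -0.01, 0.05]]
        H1, J1 = total_field_arrays(coils, [1.0, -0.5], pts)
        H2, J2 = total_field_arrays(coils, [2.0, -1.0], pts)
        np.testing.assert_allclose(H2, 2 * H1, rtol=1e-15)
        np.testing.assert_allclose(J2, 2 * J1, rtol=1e-15)


class TestLangevin:
    def test_reference_values(self):
        assert langevin(0.0) == 0.0
        assert langevin(1.0) == pytest.approx(1.0 / np.tanh(1.0) - 1.0, rel=1e-12)
        assert langevin(1e4) == pytest.approx(1.0, abs=1e-3)

    def test_taylor_branch_matches_exact_form(self):
        # at the switch point the series and the coth form agree to the
        # accuracy the cancellation-prone exact form still delivers
        x = 1e-4
        series = x / 3.0 - x**3 / 45.0
        exact = 1.0 / np.tanh(x) - 1.0 / x
        assert series == pytest.approx(exact, rel=1e-6)
        assert langevin(x * 0.999) == pytest.approx(x * 0.999 / 3.0, rel=1e-7)

    @settings(derandomize=True, max_examples=200)
    @given(st.floats(min_value=-1e6, max_value=1e6, allow_nan=False))
    def test_odd_and_bounded(self, x):
        y = langevin(x)
        assert abs(y) < 1.0 or x == 0.0
        assert y == pytest.approx(-langevin(-x), abs=1e-15)


class TestMagnetization:
    def test_limits(self, particle):
        assert magnetization(0.0, particle) == 0.0
        # saturation: M -> Ms
        assert magnetization(1e9, particle) == pytest.approx(
            particle.saturation_magnetization, rel=1e-6)

    def test_initial_slope(self, particle):
        # dM/dH -> mu0 Ms^2 V / (3 kB T) in the linear (small-H) regime;
        # for a 400 nm particle that regime ends well below 1 A/m, so the
        # finite-difference check sits at H = 1e-3 A/m
        chi = (MU0 * particle.saturation_magnetization**2 * particle.core_volume
               / (3.0 * KB * particle.temperature))
        h = 1e-3
        fd = (magnetization(h, particle) - magnetization(0.0, particle)) / h
        assert fd == pytest.approx(chi, rel=1e-4)

    def test_monotone_and_bounded(self, particle):
        H = np.logspace(-3, 7, 200)
        M = magnetization(H, particle)
        assert np.all(np.diff(M) >= 0)
        assert np.all(M >= 0) and np.all(M <= particle.saturation_magnetization)


class TestMomentCoefficient:
    def test_zero_field_limit(self, particle):
        g0 = moment_coefficient(0.0, particle)
        expected = (MU0 * particle.saturation_magnetization**2
                    * particle.core_volume**2 / (3.0 * KB * particle.temperature))
        assert g0 == pytest.approx(expected, rel=1e-12)
        # continuity: the small-H value of V M(H)/H approaches g(0)
        assert moment_coefficient(1e-3, particle) == pytest.approx(g0, rel=1e-8)

    def test_saturated_moment(self, particle):
        H = 1e9
        m = moment_coefficient(H, particle) * H
        assert m == pytest.approx(
            particle.core_volume * particle.saturation_magnetization, rel=1e-6)

    def test_nonnegative_sweep(self, particle):
        H = np.logspace(-3, 7, 100)
        assert np.all(moment_coefficient(H, particle) >= 0)


class TestMagneticForce:
    def test_zero_field(self, particle):
        sample = magnetics.FieldSample(H=np.zeros(3), jacobian=np.zeros((3, 3)))
        assert np.all(magnetic_force(sample, particle) == 0.0)

    def test_force_points_toward_coil(self, coil, particle):
        # on the axis at z > 0 the field grows toward the coil plane, so
        # the force must point in -z
        s = coil_field(coil, 1.0, [0.0, 0.0, 0.08])
        F = magnetic_force(s, particle)
        assert F[2] < 0.0
        assert abs(F[0]) < 1e-18 and abs(F[1]) < 1e-18

    def test_gradient_of_h_squared_oracle(self, coil, particle, rng):
        # F = (mu0/2) g(|H|) grad(H^2), with grad(H^2) by central differences
        h = 1e-7
        count = 0
        while count < 10:
            p = rng.uniform(-0.08, 0.08, size=3)
            rho = np.hypot(p[0], p[1])
            if np.hypot(rho - coil.radius, p[2]) < 5e-3:
                continue
            count += 1
            s = coil_field(coil, 1.0, p)
            F = magnetic_force(s, particle)
            grad = np.empty(3)
            for j in range(3):
                dp = np.zeros(3)
                dp[j] = h
                grad[j] = (np.sum(coil_field(coil, 1.0, p + dp).H**2)
                           - np.sum(coil_field(coil, 1.0, p - dp).H**2)) / (2 * h)
            g = moment_coefficient(float(np.linalg.norm(s.H)), particle)
            np.testing.assert_allclose(F, 0.5 * MU0 * g * grad,
                                       rtol=1e-4, atol=1e-4 * np.abs(F).max())

    def test_dipole_and_gradient_forms_agree(self, coil, particle, rng):
        # (m.grad)B = mu0 g J H must equal (mu0/2) g grad(H^2) = mu0 g J^T H
        # for the curl-free coil field evaluated from the same jacobian
        for _ in range(10):
            p = rng.uniform(-0.08, 0.08, size=3)
            rho = np.hypot(p[0], p[1])
            if np.hypot(rho - coil.radius, p[2]) < 5e-3:
                continue
            s = coil_field(coil, 1.0, p)
            g = moment_coefficient(float(np.linalg.norm(s.H)), particle)
            f_dipole = MU0 * g * (s.jacobian @ s.H)
            f_grad = MU0 * g * (s.jacobian.T @ s.H)
            np.testing.assert_allclose(f_dipole, f_grad,
                                       rtol=1e-10, atol=1e-10 * np.abs(f_grad).max())


class TestDriftVelocity:
    def test_zero_force_zero_flow(self):
        v = drift_velocity(np.zeros(2), viscosity=3e-3, hydrodynamic_radius=200e-9)
        assert np.all(v == 0.0)

    def test_identity_scaling(self):
        eta, rp = 3e-3, 200e-9
        zeta = 6 * np.pi * eta * rp
        v = drift_velocity(np.array([zeta, 0.0]), eta, rp)
        np.testing.assert_allclose(v, [1.0, 0.0], rtol=1e-15)

    def test_pure_flow_advection(self):
        # no magnetic force: the particle rides the diagonal flow
        flow = np.array([-3e-6, 3e-6])
        v = drift_velocity(np.zeros(2), 3e-3, 200e-9, flow=flow)
        np.testing.assert_array_equal(v, flow)

    def test_invalid_parameters(self):
        with pytest.raises(ValueError):
            drift_velocity(np.zeros(2), 0.0, 200e-9)
        with pytest.raises(ValueError):
            drift_velocity(np.zeros(2), 3e-3, -1.0)


class TestParticleSpec:
    def test_core_volume_derived(self, particle):
        assert particle.core_volume == pytest.approx(
            np.pi * (400e-9) ** 3 / 6, rel=1e-12)
        assert particle.hydrodynamic_radius == pytest.approx(200e-9)

    def test_validation(self):
        with pytest.raises(ValueError):
            ParticleSpec(core_diameter=-1e-9, saturation_magnetization=1e5)
        with pytest.raises(ValueError):
            CoilSpec(center=np.zeros(3), axis=[0, 0, 2.0], radius=0.05, turns=10)
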