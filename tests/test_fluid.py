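"""Fluid wrench model: closed-form limits, symmetries, dissipation."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from flysim.fluid import (
    AIR,
    BodyKinematics,
    EllipsoidGeom,
    FluidCoefficients,
    FluidMedium,
    added_mass_matrix,
    kutta_lift,
    lamb_coefficients,
    magnus_force,
    quadratic_drag_wrench,
    total_fluid_wrench,
    total_fluid_wrench_world,
    viscous_resistance_wrench,
)
from flysim.rotations import quat_from_axis_angle, quat_rotate

SPHERE_MM = EllipsoidGeom((1e-3, 1e-3, 1e-3))
WING = EllipsoidGeom((4.4e-4, 1.285e-3, 5e-6), span_axis=1)


def _rand_kin(rng, with_accel=False):
    return BodyKinematics(
        v=rng.normal(size=3), w=rng.normal(size=3) * 100,
        a_lin=rng.normal(size=3) * 10 if with_accel else None,
    )


class TestViscousResistance:
    def test_stokes_sphere_closed_form(self):
        beta = 1.8e-5
        kin = BodyKinematics(v=[0.1, 0, 0], w=np.zeros(3))
        w = viscous_resistance_wrench(SPHERE_MM, kin, FluidMedium(1.204, beta))
        expected = -6 * np.pi * beta * 1e-3 * 0.1
        assert w.force[0] == pytest.approx(expected, rel=1e-12)
        assert w.force[0] == pytest.approx(-3.39e-8, rel=1e-2)
        assert np.allclose(w.torque, 0.0)

    def test_rotational_stokes_sphere(self):
        kin = BodyKinematics(v=np.zeros(3), w=[0, 0, 50.0])
        w = viscous_resistance_wrench(SPHERE_MM, kin, FluidMedium(1.0, 1e-3))
        assert w.torque[2] == pytest.approx(-8 * np.pi * 1e-3 * 1e-9 * 50.0)

    def test_zero_state_zero_wrench(self):
        kin = BodyKinematics(v=np.zeros(3), w=np.zeros(3))
        w = viscous_resistance_wrench(WING, kin, AIR)
        assert np.allclose(w.force, 0) and np.allclose(w.torque, 0)

    def test_linearity_in_velocity(self, rng):
        k1 = _rand_kin(rng)
        k2 = BodyKinematics(v=2 * k1.v, w=2 * k1.w)
        w1 = viscous_resistance_wrench(WING, k1, AIR)
        w2 = viscous_resistance_wrench(WING, k2, AIR)
        assert np.allclose(w2.force, 2 * w1.force)
        assert np.allclose(w2.torque, 2 * w1.torque)


class TestQuadraticDrag:
    def test_zero_velocity_zero_force(self):
        kin = BodyKinematics(v=np.zeros(3), w=np.zeros(3))
        w = quadratic_drag_wrench(WING, kin, AIR, FluidCoefficients())
        assert np.allclose(w.force, 0)

    def test_dissipative_on_random_states(self, rng):
        c = FluidCoefficients()
        for _ in range(1000):
            kin = _rand_kin(rng)
            w = quadratic_drag_wrench(WING, kin, AIR, c)
            assert w.force @ kin.v <= 1e-18
            assert w.torque @ kin.w <= 1e-18

    def test_density_linearity(self, rng):
        kin = _rand_kin(rng)
        w1 = quadratic_drag_wrench(WING, kin, FluidMedium(1.2, 0.0),
                                   FluidCoefficients())
        w2 = quadratic_drag_wrench(WING, kin, FluidMedium(2.4, 0.0),
                                   FluidCoefficients())
        assert np.allclose(w2.force, 2 * w1.force)
        assert np.allclose(w2.torque, 2 * w1.torque)

    def test_speed_squared_scaling(self, rng):
        kin = BodyKinematics(v=rng.normal(size=3), w=np.zeros(3))
        kin2 = BodyKinematics(v=3 * kin.v, w=np.zeros(3))
        w1 = quadratic_drag_wrench(WING, kin, AIR, FluidCoefficients())
        w2 = quadratic_drag_wrench(WING, kin2, AIR, FluidCoefficients())
        assert np.allclose(w2.force, 9 * w1.force)


class TestMagnus:
    def test_parallel_spin_gives_zero(self):
        kin = BodyKinematics(v=[1.0, 0, 0], w=[200.0, 0, 0])
        f = magnus_force(SPHERE_MM, kin, AIR, FluidCoefficients())
        assert np.allclose(f, 0)

    def test_sphere_closed_form(self):
        # F = c rho V (w x v): 1.2 * 4.19e-9 * (0, 100, 0)
        kin = BodyKinematics(v=[1.0, 0, 0], w=[0, 0, 100.0])
        f = magnus_force(
            SPHERE_MM, kin, FluidMedium(1.2, 0.0),
            FluidCoefficients(magnus_lift=1.0),
        )
        v_sphere = 4.0 / 3.0 * np.pi * 1e-9
        assert f[1] == pytest.approx(1.2 * v_sphere * 100.0, rel=1e-12)
        assert f[1] == pytest.approx(5.03e-7, rel=1e-2)
        assert f[0] == 0 and f[2] == 0

    def test_always_perpendicular_to_v_and_w(self, rng):
        for _ in range(100):
            kin = _rand_kin(rng)
            f = magnus_force(WING, kin, AIR, FluidCoefficients())
            assert abs(f @ kin.v) < 1e-12 * max(np.linalg.norm(f), 1e-30) * 1e6
            assert abs(f @ kin.w) < 1e-9


class TestKutta:
    def test_edgewise_motion_gives_zero(self):
        # motion along the chord (x axis): angle of attack 0
        kin = BodyKinematics(v=[1.0, 0, 0], w=np.zeros(3))
        assert np.allclose(kutta_lift(WING, kin, AIR, FluidCoefficients()), 0)

    def test_zero_speed_gives_zero(self):
        kin = BodyKinematics(v=np.zeros(3), w=np.zeros(3))
        assert np.allclose(kutta_lift(WING, kin, AIR, FluidCoefficients()), 0)

    def test_broadside_motion_gives_zero(self):
        kin = BodyKinematics(v=[0, 0, 1.0], w=np.zeros(3))
        f = kutta_lift(WING, kin, AIR, FluidCoefficients())
        assert np.allclose(f, 0, atol=1e-20)

    def test_peak_at_45_degrees(self):
        # dense 0.1-degree sweep of the angle of attack
        alphas = np.arange(0.1, 90.0, 0.1)
        mags = []
        for a in alphas:
            r = np.deg2rad(a)
            kin = BodyKinematics(v=[np.cos(r), 0, np.sin(r)], w=np.zeros(3))
            mags.append(
                np.linalg.norm(kutta_lift(WING, kin, AIR, FluidCoefficients()))
            )
        assert alphas[int(np.argmax(mags))] == pytest.approx(45.0, abs=0.1)

    def test_perpendicular_to_velocity(self, rng):
        for _ in range(100):
            kin = BodyKinematics(v=rng.normal(size=3), w=np.zeros(3))
            f = kutta_lift(WING, kin, AIR, FluidCoefficients())
            assert abs(f @ kin.v) < 1e-9 * max(1.0, np.linalg.norm(f))


class TestAddedMass:
    def test_sphere_half_rho_v(self):
        m = added_mass_matrix(SPHERE_MM, FluidMedium(1000.0, 0.0))
        expected = 0.5 * 1000.0 * 4.0 / 3.0 * np.pi * 1e-9
        assert np.allclose(np.diag(m)[:3], expected, rtol=1e-4)
        assert np.allclose(np.diag(m)[3:], 0.0, atol=1e-15)

    def test_thin_disc_limit(self):
        # broadside added mass of a disc radius R: (8/3) rho R^3
        disc = EllipsoidGeom((1.0, 1.0, 1e-4))
        m = added_mass_matrix(disc, FluidMedium(1.0, 0.0))
        assert m[2, 2] == pytest.approx(8.0 / 3.0, rel=1e-3)

    def test_zero_density_zero_matrix(self):
        with pytest.raises(ValueError):
            FluidMedium(0.0, 0.0)
        # density scaling: matrix is proportional to rho
        m1 = added_mass_matrix(WING, FluidMedium(1.0, 0.0))
        m2 = added_mass_matrix(WING, FluidMedium(2.0, 0.0))
        assert np.allclose(m2, 2 * m1)

    def test_psd_for_random_ellipsoids(self, rng):
        for _ in range(20):
            g = EllipsoidGeom(tuple(rng.uniform(1e-4, 1e-2, 3)))
            m = added_mass_matrix(g, AIR)
            assert np.all(np.linalg.eigvalsh(m) >= -1e-18)

    def test_lamb_coefficients_sum_to_two(self, rng):
        for _ in range(10):
            g = EllipsoidGeom(tuple(rng.uniform(1e-4, 1e-2, 3)))
            assert lamb_coefficients(g).sum() == pytest.approx(2.0, rel=1e-9)


class TestTotalWrench:
    def test_all_off_gives_zero(self):
        c = FluidCoefficients(0, 0, 0, 0, 0)
        kin = BodyKinematics(v=[1.0, 2, 3], w=[4.0, 5, 6])
        total, _ = total_fluid_wrench(WING, kin, FluidMedium(1.2, 0.0), c)
        assert np.allclose(total.force, 0) and np.allclose(total.torque, 0)

    def test_additivity_of_breakdown(self, rng):
        kin = _rand_kin(rng, with_accel=True)
        total, bd = total_fluid_wrench(WING, kin, AIR, FluidCoefficients())
        f = sum(w.force for w in bd.values())
        t = sum(w.torque for w in bd.values())
        assert np.allclose(total.force, f) and np.allclose(total.torque, t)

    def test_rotation_equivariance(self, rng):
        for _ in range(20):
            axis = rng.normal(size=3)
            q = quat_from_axis_angle(axis, rng.uniform(0, np.pi))
            v = rng.normal(size=3)
            w = rng.normal(size=3) * 100
            g0 = EllipsoidGeom(WING.semi_axes, span_axis=1)
            w0, _ = total_fluid_wrench_world(g0, v, w, AIR, FluidCoefficients())
            g1 = EllipsoidGeom(WING.semi_axes, span_axis=1, pose_quat=q)
            w1, _ = total_fluid_wrench_world(
                g1, quat_rotate(q, v), quat_rotate(q, w), AIR,
                FluidCoefficients(),
            )
            scale = max(np.linalg.norm(w0.force), 1e-30)
            assert np.linalg.norm(
                w1.force - quat_rotate(q, w0.force)
            ) < 1e-10 * scale
            tscale = max(np.linalg.norm(w0.torque), 1e-30)
            assert np.linalg.norm(
                w1.torque - quat_rotate(q, w0.torque)
            ) < 1e-10 * tscale

    def test_mirror_symmetry(self, rng):
        # reflect kinematics across the xz-plane: v_y flips, w_x / w_z flip
        m = np.array([1.0, -1.0, 1.0])
        for _ in range(20):
            v = rng.normal(size=3)
            w = rng.normal(size=3) * 50
            kin = BodyKinematics(v=v, w=w)
            kin_m = BodyKinematics(v=m * v, w=-m * w)
            t0, _ = total_fluid_wrench(WING, kin, AIR, FluidCoefficients())
            t1, _ = total_fluid_wrench(WING, kin_m, AIR, FluidCoefficients())
            assert np.allclose(t1.force, m * t0.force, atol=1e-12)
            assert np.allclose(t1.torque, -m * t0.torque, atol=1e-12)

    def test_drag_dissipates_with_lift_off(self, rng):
        c = FluidCoefficients(kutta_lift=0.0, magnus_lift=0.0)
        for _ in range(200):
            kin = _rand_kin(rng)
            total, _ = total_fluid_wrench(WING, kin, AIR, c)
            assert total.power(kin) <= 1e-15


@given(
    st.floats(0.1, 10.0), st.floats(0.1, 10.0), st.floats(0.1, 10.0),
)
def test_projected_area_bounded_by_extremes(a, b, c):
    """The silhouette area along any axis lies between the smallest and
    largest principal cross-sections."""
    g = EllipsoidGeom((a, b, c))
    s = sorted((a, b, c))
    lo, hi = np.pi * s[0] * s[1], np.pi * s[1] * s[2]
    for d in (np.array([1.0, 0, 0]), np.array([0.3, -0.5, 0.8])):
        area = g.projected_area(d)
        assert lo - 1e-9 <= area <= hi + 1e-9
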