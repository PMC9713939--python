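"""Unit and property tests of the two-link rigid-body model."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dipsway import (
    AnthropometricParameters,
    JointState,
    com_and_vip,
    coriolis_matrix,
    energies,
    forward_dynamics,
    gravity_stiffness_linearized,
    gravity_torque,
    inertia_matrix,
)

REF = math.pi / 2

angles = st.floats(-1.2, 1.2)
velocities = st.floats(-3.0, 3.0)


def states():
    return st.builds(
        JointState,
        q1=st.floats(REF - 1.0, REF + 1.0),
        q2=angles,
        q1dot=velocities,
        q2dot=velocities,
    )


class TestInertiaMatrix:
    def test_entries_match_hand_evaluated_constants(self, anthro):
        # independent oracle: recompute A, B, D from the raw segment values
        m1, m2, L1, r1, r2 = anthro.m1, anthro.m2, anthro.L1, anthro.r1, anthro.r2
        I1, I2 = m1 * r1**2, m2 * r2**2
        A = I1 + I2 + m1 * r1**2 + m2 * (L1**2 + r2**2)
        B = m2 * L1 * r2
        D = I2 + m2 * r2**2
        m = inertia_matrix(JointState(q1=REF, q2=0.0), anthro)
        assert m == pytest.approx(np.array([[A + 2 * B, D + B], [D + B, D]]), rel=1e-12)
        m90 = inertia_matrix(JointState(q1=REF, q2=math.pi / 2), anthro)
        assert m90[0, 0] == pytest.approx(A, rel=1e-12)
        assert m90[0, 1] == pytest.approx(D, rel=1e-12)

    @pytest.mark.parametrize("q2", np.linspace(-math.pi / 2, math.pi / 2, 9))
    def test_symmetric_positive_definite(self, q2, anthro):
        m = inertia_matrix(JointState(q2=float(q2)), anthro)
        assert m[0, 1] == m[1, 0]
        assert np.min(np.linalg.eigvalsh(m)) > 0.0


class TestCoriolisMatrix:
    def test_zero_without_velocity_or_bend(self, anthro):
        assert np.all(coriolis_matrix(JointState(q2=0.7), anthro) == 0.0)
        assert np.all(
            coriolis_matrix(JointState(q2=0.0, q1dot=2.0, q2dot=-1.0), anthro)[1] == 0.0
        )

    @settings(deadline=None, max_examples=50)
    @given(q=states())
    def test_mdot_minus_2c_skew_symmetric(self, q):
        anthro = AnthropometricParameters()
        h = 1e-7
        # M depends on q2 only; dM/dt = dM/dq2 * q2dot by the chain rule
        mp = inertia_matrix(JointState(q2=q.q2 + h), anthro)
        mm = inertia_matrix(JointState(q2=q.q2 - h), anthro)
        mdot = (mp - mm) / (2 * h) * q.q2dot
        s = mdot - 2.0 * coriolis_matrix(q, anthro)
        assert np.allclose(s + s.T, 0.0, atol=1e-6)


class TestGravityTorque:
    def test_zero_at_reference(self, anthro, reference):
        assert np.allclose(gravity_torque(reference, anthro), 0.0, atol=1e-12)

    @settings(deadline=None, max_examples=30)
    @given(a=st.floats(-0.5, 0.5), b=st.floats(-0.5, 0.5))
    def test_mirror_antisymmetry(self, a, b):
        anthro = AnthropometricParameters()
        g_pos = gravity_torque(JointState(q1=REF + a, q2=b), anthro)
        g_neg = gravity_torque(JointState(q1=REF - a, q2=-b), anthro)
        assert np.allclose(g_pos, -g_neg, atol=1e-9)

    def test_destabilizing_direction(self, anthro):
        # a forward lean must be accelerated further forward by gravity alone
        tilted = JointState(q1=REF - 0.05)
        acc = forward_dynamics(tilted, np.zeros(2), anthro)
        assert acc[0] < 0.0


class TestLinearization:
    def test_jacobian_matches_finite_differences(self, anthro, reference):
        jac, _ = gravity_stiffness_linearized(anthro)
        h = 1e-6
        fd = np.empty((2, 2))
        for j, dq in enumerate(np.eye(2) * h):
            gp = gravity_torque(JointState(q1=REF + dq[0], q2=dq[1]), anthro)
            gm = gravity_torque(JointState(q1=REF - dq[0], q2=-dq[1]), anthro)
            fd[:, j] = (gp - gm) / (2 * h)
        assert np.allclose(jac, fd, rtol=1e-6, atol=1e-4)

    def test_linearization_error_is_second_order(self, anthro):
        jac, _ = gravity_stiffness_linearized(anthro)

        def residual(eps):
            dq = np.array([eps, -eps])
            g = gravity_torque(JointState(q1=REF + dq[0], q2=dq[1]), anthro)
            return np.linalg.norm(g - jac @ dq)

        r1, r2 = residual(2e-3), residual(1e-3)
        # gravity is odd about the reference (pure cosines), so the leading
        # residual is cubic: halving the displacement divides it by 8
        assert r1 / r2 == pytest.approx(8.0, rel=0.1)

    def test_critical_stiffness_values(self, anthro):
        _, (k_a, k_h) = gravity_stiffness_linearized(anthro)
        assert k_h == pytest.approx(175.0, rel=5e-3)
        assert 2 * k_h == pytest.approx(350.0, rel=5e-3)
        assert k_a == 654.0  # configured reference constant
        assert anthro.critical_ankle_stiffness_derived == pytest.approx(829.0, rel=5e-3)


class TestComAndVip:
    @settings(deadline=None, max_examples=50)
    @given(q1=st.floats(0.3, math.pi - 0.3))
    def test_collinear_links_give_qcom_equal_q1(self, q1):
        anthro = AnthropometricParameters()
        vip = com_and_vip(JointState(q1=q1, q2=0.0), anthro)
        assert vip.q_com == pytest.approx(q1, abs=1e-12)

    def test_reference_posture(self, anthro, reference):
        vip = com_and_vip(reference, anthro)
        assert vip.q_com == pytest.approx(REF, abs=1e-12)
        assert vip.y_com == pytest.approx(0.0, abs=1e-12)

    def test_against_per_link_kinematics(self, anthro):
        # independent oracle: sum the two segment CoMs explicitly
        q = JointState(q1=REF + 0.05, q2=-0.1)
        p = anthro
        leg = np.array([p.r1 * math.cos(q.q1), p.r1 * math.sin(q.q1)])
        hat = np.array(
            [
                p.L1 * math.cos(q.q1) + p.r2 * math.cos(q.q1 + q.q2),
                p.L1 * math.sin(q.q1) + p.r2 * math.sin(q.q1 + q.q2),
            ]
        )
        com = (p.m1 * leg + p.m2 * hat) / p.m_tot
        vip = com_and_vip(q, anthro)
        assert vip.q_com == pytest.approx(math.atan2(com[1], com[0]), abs=1e-12)
        assert np.hypot(vip.y_com, vip.z_com) == pytest.approx(np.linalg.norm(com), rel=1e-12)
        # CoM distance bounds
        dist = np.hypot(vip.y_com, vip.z_com)
        assert p.r1 * p.m1 / p.m_tot < dist < p.L1 + p.L2


class TestForwardDynamicsAndEnergies:
    def test_equilibrium_at_reference(self, anthro, reference):
        assert np.allclose(forward_dynamics(reference, np.zeros(2), anthro), 0.0, atol=1e-11)

    @settings(deadline=None, max_examples=50)
    @given(q=states(), t1=st.floats(-50, 50), t2=st.floats(-50, 50))
    def test_defining_identity(self, q, t1, t2):
        anthro = AnthropometricParameters()
        tau = np.array([t1, t2])
        acc = forward_dynamics(q, tau, anthro)
        resid = (
            inertia_matrix(q, anthro) @ acc
            + coriolis_matrix(q, anthro) @ q.qdot
            - gravity_torque(q, anthro)
            - tau
        )
        assert np.allclose(resid, 0.0, atol=1e-9)

    @settings(deadline=None, max_examples=50)
    @given(q=states())
    def test_kinetic_energy_matches_per_link_velocities(self, q):
        anthro = AnthropometricParameters()
        p = anthro
        # oracle: differentiate each link CoM position analytically
        v_leg = p.r1 * q.q1dot * np.array([-math.sin(q.q1), math.cos(q.q1)])
        w12 = q.q1dot + q.q2dot
        v_hat = np.array(
            [
                -p.L1 * math.sin(q.q1) * q.q1dot - p.r2 * math.sin(q.q1 + q.q2) * w12,
                p.L1 * math.cos(q.q1) * q.q1dot + p.r2 * math.cos(q.q1 + q.q2) * w12,
            ]
        )
        t_oracle = (
            0.5 * p.m1 * v_leg @ v_leg
            + 0.5 * p.I1 * q.q1dot**2
            + 0.5 * p.m2 * v_hat @ v_hat
            + 0.5 * p.I2 * w12**2
        )
        t, _ = energies(q, anthro)
        assert t == pytest.approx(t_oracle, rel=1e-9, abs=1e-12)

    def test_potential_energy_maximal_at_reference(self, anthro, reference):
        _, u_ref = energies(reference, anthro)
        expected = anthro.g * (
            anthro.m1 * anthro.r1 + anthro.m2 * (anthro.L1 + anthro.r2)
        )
        assert u_ref == pytest.approx(expected, rel=1e-12)
        for dq1, dq2 in [(0.1, 0.0), (-0.1, 0.1), (0.05, -0.2)]:
            _, u = energies(JointState(q1=REF + dq1, q2=dq2), anthro)
            assert u < u_ref
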