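"""Rigid-body model of the sagittal double inverted pendulum (DIP).

The standing body is reduced to two links hinged at the ankle and the hip:
the legs (link 1) and the head-arms-trunk segment, HAT (link 2).  The ankle
angle ``q1`` is measured from the ground plane, so the upright reference
posture is ``q1 = pi/2``; the hip angle ``q2`` is the relative inter-segment
angle, zero at reference.  All angles are radians internally.

Besides the usual manipulator quantities (inertia matrix ``M``, Coriolis
matrix ``C``, gravity torque ``G``, energies) this module provides the
kinematics of the *virtual inverted pendulum* (VIP): the virtual link from
the ankle to the whole-body centre of mass, whose angle ``q_com`` is the
feedback variable of the intermittent controller.

Sign convention for gravity: ``gravity_torque`` returns the destabilizing
generalized torque ``-dU/dq``, which enters the equation of motion with a
plus sign::

    M(q) q̈ = tau - C(q, q̇) q̇ + G(q)

so that at the reference posture (where G = 0) zero torque is an exact
equilibrium, and any tilt is accelerated away from vertical.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "AnthropometricParameters",
    "JointState",
    "VIPState",
    "inertia_matrix",
    "coriolis_matrix",
    "gravity_torque",
    "gravity_stiffness_linearized",
    "com_and_vip",
    "forward_dynamics",
    "energies",
]

#: Default gravitational acceleration, m/s^2.
G_DEFAULT = 9.81


@dataclass(frozen=True)
class AnthropometricParameters:
    """Segment masses, lengths and inertias of the two-link standing body.

    Defaults describe a young adult male of 84.14 kg and 1.78 m: the legs
    carry one third of the body mass, the HAT the remaining two thirds.
    Moments of inertia are the point-mass values ``I = m r**2`` about each
    segment's own centre of mass, recomputed from mass and CoM offset so the
    invariant holds exactly.

    Attributes
    ----------
    m1, m2 : float
        Leg and HAT masses, kg.
    L1, L2 : float
        Leg and HAT lengths, m.
    r1, r2 : float
        CoM offsets of each segment from its proximal joint, m.
    g : float
        Gravitational acceleration, m/s^2.
    critical_ankle_stiffness : float
        Reference critical ankle stiffness, Nm/rad (configurable constant;
        see also :attr:`critical_ankle_stiffness_derived`).
    """

    m1: float = 28.047
    m2: float = 56.093
    L1: float = 0.9
    L2: float = 0.88
    r1: float = 0.576
    r2: float = 0.318
    g: float = G_DEFAULT
    critical_ankle_stiffness: float = 654.0

    def __post_init__(self) -> None:
        if not (0.0 < self.r1 < self.L1):
            raise ValueError(f"r1 must lie in (0, L1); got r1={self.r1}, L1={self.L1}")
        if not (0.0 < self.r2 < self.L2):
            raise ValueError(f"r2 must lie in (0, L2); got r2={self.r2}, L2={self.L2}")
        if min(self.m1, self.m2, self.g) <= 0.0:
            raise ValueError("masses and g must be positive")

    @property
    def m_tot(self) -> float:
        """Total body mass, kg."""
        return self.m1 + self.m2

    @property
    def I1(self) -> float:
        """Leg moment of inertia about its own CoM, kg m^2."""
        return self.m1 * self.r1**2

    @property
    def I2(self) -> float:
        """HAT moment of inertia about its own CoM, kg m^2."""
        return self.m2 * self.r2**2

    # Inertia constants of the DIP equations of motion.
    @property
    def A(self) -> float:
        return self.I1 + self.I2 + self.m1 * self.r1**2 + self.m2 * (self.L1**2 + self.r2**2)

    @property
    def B(self) -> float:
        return self.m2 * self.L1 * self.r2

    @property
    def D(self) -> float:
        return self.I2 + self.m2 * self.r2**2

    @property
    def L_com(self) -> float:
        """Distance from the ankle to the whole-body CoM at reference, m."""
        return (self.m1 * self.r1 + self.m2 * (self.L1 + self.r2)) / self.m_tot

    @property
    def critical_hip_stiffness(self) -> float:
        """Critical hip stiffness g*m2*r2, Nm/rad."""
        return self.g * self.m2 * self.r2

    @property
    def critical_ankle_stiffness_derived(self) -> float:
        """Critical ankle stiffness g*m_tot*L_com from these segment values, Nm/rad."""
        return self.g * self.m_tot * self.L_com


@dataclass(frozen=True)
class JointState:
    """Joint angles (rad) and angular velocities (rad/s) of the DIP."""

    q1: float = math.pi / 2
    q2: float = 0.0
    q1dot: float = 0.0
    q2dot: float = 0.0

    def __post_init__(self) -> None:
        vals = (self.q1, self.q2, self.q1dot, self.q2dot)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError(f"joint state must be finite, got {vals}")

    @classmethod
    def reference(cls) -> "JointState":
        return cls()

    @property
    def q(self) -> np.ndarray:
        return np.array([self.q1, self.q2])

    @property
    def qdot(self) -> np.ndarray:
        return np.array([self.q1dot, self.q2dot])


@dataclass(frozen=True)
class VIPState:
    """Virtual-inverted-pendulum state: CoM angle seen from the ankle.

    ``y_com``/``z_com`` are the horizontal and vertical CoM coordinates in
    the sagittal plane, m; ``q_com`` their polar angle (rad, reference
    pi/2); ``q_com_dot`` its angular velocity (rad/s), zero when the state
    was built from position alone.
    """

    q_com: float
    q_com_dot: float = 0.0
    y_com: float = field(default=float("nan"))
    z_com: float = field(default=float("nan"))


def inertia_matrix(q: JointState, p: AnthropometricParameters) -> np.ndarray:
    """2x2 symmetric positive-definite inertia matrix M(q), kg m^2."""
    c2 = math.cos(q.q2)
    off = p.D + p.B * c2
    return np.array([[p.A + 2.0 * p.B * c2, off], [off, p.D]])


def coriolis_matrix(q: JointState, p: AnthropometricParameters) -> np.ndarray:
    """Coriolis/centrifugal matrix C(q, q̇) such that C q̇ is the velocity torque.

    Derived from the kinetic energy; satisfies the skew-symmetry of
    ``dM/dt - 2C``.
    """
    bs2 = p.B * math.sin(q.q2)
    return np.array(
        [
            [-bs2 * q.q2dot, -bs2 * (q.q1dot + q.q2dot)],
            [bs2 * q.q1dot, 0.0],
        ]
    )


def gravity_torque(q: JointState, p: AnthropometricParameters) -> np.ndarray:
    """Destabilizing gravity torque -dU/dq, Nm.

    Exactly zero at the reference posture; enters the forward dynamics with
    a plus sign (see module docstring).
    """
    c1 = math.cos(q.q1)
    c12 = math.cos(q.q1 + q.q2)
    w1 = p.m1 * p.r1 + p.m2 * p.L1
    w2 = p.m2 * p.r2
    return -p.g * np.array([w1 * c1 + w2 * c12, w2 * c12])


def gravity_stiffness_linearized(
    p: AnthropometricParameters,
) -> tuple[np.ndarray, tuple[float, float]]:
    """Linearized gravity about the reference posture and critical stiffnesses.

    Returns
    -------
    J : (2, 2) ndarray
        Jacobian of :func:`gravity_torque` with respect to (dq1, dq2) at the
        reference posture, Nm/rad.  ``G(ref + dq) ≈ J @ dq``.
    (K_a_crit, K_h_crit) : tuple of float
        Critical ankle and hip stiffness, Nm/rad.  ``K_h_crit = g*m2*r2``;
        ``K_a_crit`` is the configured reference constant (the value derived
        from the segment parameters is ``p.critical_ankle_stiffness_derived``).
    """
    w1 = p.m1 * p.r1 + p.m2 * p.L1
    w2 = p.m2 * p.r2
    jac = p.g * np.array([[w1 + w2, w2], [w2, w2]])
    return jac, (p.critical_ankle_stiffness, p.critical_hip_stiffness)


def com_and_vip(q: JointState, p: AnthropometricParameters) -> VIPState:
    """Whole-body CoM coordinates and VIP angle for a given posture.

    The VIP angle shares the convention of ``q1``: pi/2 at reference, and
    ``q_com == q1`` whenever the two links are collinear (``q2 == 0``).
    The returned angular velocity is zero (velocity is estimated by the
    simulator from the angle series).
    """
    c1, s1 = math.cos(q.q1), math.sin(q.q1)
    c12, s12 = math.cos(q.q1 + q.q2), math.sin(q.q1 + q.q2)
    w1 = (p.m1 * p.r1 + p.m2 * p.L1) / p.m_tot
    w2 = (p.m2 * p.r2) / p.m_tot
    y = w1 * c1 + w2 * c12
    z = w1 * s1 + w2 * s12
    return VIPState(q_com=math.atan2(z, y), q_com_dot=0.0, y_com=y, z_com=z)


def forward_dynamics(
    q: JointState, tau_total: np.ndarray, p: AnthropometricParameters
) -> np.ndarray:
    """Joint angular accelerations, rad/s^2.

    Solves ``M(q) q̈ = tau_total - C(q, q̇) q̇ + G(q)`` where ``tau_total``
    aggregates bias, stiffness, intermittent and noise torques and ``G`` is
    the destabilizing gravity torque of :func:`gravity_torque`.
    """
    m = inertia_matrix(q, p)
    det = m[0, 0] * m[1, 1] - m[0, 1] * m[1, 0]
    if abs(det) < 1e-12:
        raise np.linalg.LinAlgError("degenerate inertia matrix")
    rhs = np.asarray(tau_total, dtype=float) - coriolis_matrix(q, p) @ q.qdot + gravity_torque(q, p)
    return np.linalg.solve(m, rhs)


def energies(q: JointState, p: AnthropometricParameters) -> tuple[float, float]:
    """Kinetic and potential energy (T, U), J.

    T is the quadratic form ``q̇ᵀ M(q) q̇ / 2``; U is ``g`` times the summed
    CoM heights of the two segments (zero level at the ankle).
    """
    t = 0.5 * float(q.qdot @ inertia_matrix(q, p) @ q.qdot)
    s1 = math.sin(q.q1)
    s12 = math.sin(q.q1 + q.q2)
    z1 = p.r1 * s1
    z2 = p.L1 * s1 + p.r2 * s12
    u = p.g * (p.m1 * z1 + p.m2 * z2)
    return t, u
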