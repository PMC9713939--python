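"""JIT-compiled per-step integration loop of the controlled DIP.

Kept free of Python objects so numba can compile it; the public interface
is :func:`dipsway.simulator.simulate`, which unpacks the configuration into
the scalar/array arguments used here.  The loop mirrors, step by step, the
torque composition documented in :mod:`dipsway.control` and the forward
Euler scheme of :mod:`dipsway.simulator`.
"""

from __future__ import annotations

import math

import numpy as np
from numba import njit


@njit(fastmath=False)
def step_loop(
    n: int,
    dt: float,
    delay_steps: int,
    A: float,
    B: float,
    D: float,
    w1: float,  # m1*r1 + m2*L1, kg m
    w2: float,  # m2*r2, kg m
    g: float,
    K_a: float,
    B_a: float,
    K_h: float,
    B_h: float,
    q1_ref: float,
    q2_ref: float,
    P_a: float,
    D_a: float,
    P_h: float,
    D_h: float,
    phi: float,
    sigma: float,  # <= 0 disables soft clipping
    tau_b1: float,
    tau_b2: float,
    noise1: np.ndarray,
    noise2: np.ndarray,
    q1_0: float,
    q2_0: float,
    q1dot_0: float,
    q2dot_0: float,
    q_com_ref: float,
    fall_threshold: float,
):
    q1 = np.empty(n)
    q2 = np.empty(n)
    q1dot = np.empty(n)
    q2dot = np.empty(n)
    q1ddot = np.empty(n)
    q2ddot = np.empty(n)
    q_com = np.empty(n)
    q_com_dot = np.empty(n)
    tau_grav = np.empty((2, n))
    tau_stiff = np.empty((2, n))
    tau_int = np.empty((2, n))
    switch = np.zeros(n, dtype=np.uint8)

    x1 = q1_0
    x2 = q2_0
    v1 = q1dot_0
    v2 = q2dot_0
    fell_at = -1

    for k in range(n):
        c1 = math.cos(x1)
        s1 = math.sin(x1)
        c12 = math.cos(x1 + x2)
        s12 = math.sin(x1 + x2)
        c2 = math.cos(x2)
        s2 = math.sin(x2)

        # VIP reconstruction and backward-difference velocity estimate.
        qc = math.atan2(w1 * s1 + w2 * s12, w1 * c1 + w2 * c12)
        q_com[k] = qc
        q_com_dot[k] = 0.0 if k == 0 else (qc - q_com[k - 1]) / dt

        # Delayed VIP error; during warm-up the buffer holds the initial state.
        j = k - delay_steps
        if j < 0:
            j = 0
        dq = q_com_ref - q_com[j]
        dqd = -q_com_dot[j]

        a_s = 0.0
        h_s = 0.0
        if dq * (dqd + phi * dq) > 0.0:
            switch[k] = 1
            a_s = P_a * dq + D_a * dqd
            h_s = P_h * dq + D_h * dqd
            if sigma > 0.0:
                den = 3.0 * sigma * sigma
                if a_s > sigma:
                    a_s = sigma - sigma**3 / den
                elif a_s < -sigma:
                    a_s = -sigma + sigma**3 / den
                else:
                    a_s = a_s - a_s**3 / den

        g1 = -g * (w1 * c1 + w2 * c12)
        g2 = -g * w2 * c12
        ts1 = -(K_a * (x1 - q1_ref) + B_a * v1)
        ts2 = -(K_h * (x2 - q2_ref) + B_h * v2)
        # Coriolis torque C(q, q̇) q̇.
        bs2 = B * s2
        cor1 = -bs2 * v2 * v1 - bs2 * (v1 + v2) * v2
        cor2 = bs2 * v1 * v1

        rhs1 = tau_b1 + ts1 + a_s + noise1[k] + g1 - cor1
        rhs2 = tau_b2 + ts2 + h_s + noise2[k] + g2 - cor2

        m11 = A + 2.0 * B * c2
        m12 = D + B * c2
        det = m11 * D - m12 * m12
        acc1 = (D * rhs1 - m12 * rhs2) / det
        acc2 = (m11 * rhs2 - m12 * rhs1) / det

        q1[k] = x1
        q2[k] = x2
        q1dot[k] = v1
        q2dot[k] = v2
        q1ddot[k] = acc1
        q2ddot[k] = acc2
        tau_grav[0, k] = g1
        tau_grav[1, k] = g2
        tau_stiff[0, k] = ts1
        tau_stiff[1, k] = ts2
        tau_int[0, k] = a_s
        tau_int[1, k] = h_s

        if abs(qc - q_com_ref) > fall_threshold:
            fell_at = k
            break

        # Forward Euler advance.
        x1 += dt * v1
        x2 += dt * v2
        v1 += dt * acc1
        v2 += dt * acc2

    return (
        q1,
        q2,
        q1dot,
        q2dot,
        q1ddot,
        q2ddot,
        q_com,
        q_com_dot,
        tau_grav,
        tau_stiff,
        tau_int,
        switch,
        fell_at,
    )
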