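"""Torque generators stabilizing the DIP about the upright reference.

Four contributions sum into the total control torque:

* a constant feed-forward **bias** torque cancelling gravity at the
  reference posture (zero for a fully vertical reference);
* a passive **stiffness/damping** torque per joint (muscle-tendon
  visco-elasticity), with the ankle stiffness deliberately *under* its
  critical value and the hip stiffness *above* its critical value;
* the active **intermittent PD** torque: a delayed proportional-derivative
  feedback of the VIP error, switched on only in the "unsafe" regions of
  the VIP phase plane (first/third quadrants widened by the slice
  parameter Phi), optionally soft-clipped at the ankle;
* band-limited Gaussian **noise** torque emulating motor/sensor
  variability.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import signal

from .dynamics import AnthropometricParameters, JointState, VIPState, gravity_torque

__all__ = [
    "StiffnessParameters",
    "IntermittentGains",
    "VIPError",
    "SaturationParameters",
    "NoiseConfig",
    "bias_torque",
    "stiffness_torque",
    "vip_error",
    "switch_active",
    "intermittent_torque",
    "soft_clip",
    "make_noise",
]


@dataclass(frozen=True)
class StiffnessParameters:
    """Passive joint stiffness and damping.

    K_a, K_h in Nm/rad; B_a, B_h in Nms/rad.  ``mu_h`` records the hip
    stiffness as a multiple of the critical hip stiffness when the
    parameters were built that way (informational otherwise).
    """

    K_a: float = 523.0
    B_a: float = 30.0
    K_h: float = 350.0
    B_h: float = 44.0
    mu_h: Optional[float] = None

    def __post_init__(self) -> None:
        if min(self.K_a, self.B_a, self.K_h, self.B_h) < 0.0:
            raise ValueError("stiffness and damping constants must be non-negative")

    @classmethod
    def from_mu_h(
        cls,
        mu_h: float,
        p: AnthropometricParameters,
        K_a: float = 523.0,
        B_a: float = 30.0,
        B_h: float = 44.0,
    ) -> "StiffnessParameters":
        """Hip stiffness as a multiple ``mu_h`` of the critical value g*m2*r2."""
        return cls(K_a=K_a, B_a=B_a, K_h=mu_h * p.critical_hip_stiffness, B_h=B_h, mu_h=mu_h)


@dataclass(frozen=True)
class IntermittentGains:
    """PD gains of the intermittent controller and switching-slice parameter.

    A pure ankle strategy has ``P_h = D_h = 0``; a pure hip strategy has
    ``P_a = D_a = 0``; mixed strategies set all four.  Defaults are the
    mid-range pure ankle strategy.
    """

    P_a: float = 875.0
    D_a: float = 125.0
    P_h: float = 0.0
    D_h: float = 0.0
    phi: float = 0.4

    def __post_init__(self) -> None:
        if min(self.P_a, self.D_a, self.P_h, self.D_h) < 0.0:
            raise ValueError("intermittent gains must be non-negative")


@dataclass(frozen=True)
class VIPError:
    """Delayed VIP error: dq = q_ref - q_com(t - delta), dqdot likewise."""

    dq: float
    dqdot: float


@dataclass(frozen=True)
class SaturationParameters:
    """Soft-clipping threshold for the ankle intermittent torque, Nm."""

    sigma: float

    def __post_init__(self) -> None:
        if self.sigma <= 0.0:
            raise ValueError("saturation threshold sigma must be positive")

    @property
    def delta_den(self) -> float:
        """Cubic-term denominator 3*sigma**2."""
        return 3.0 * self.sigma**2


@dataclass(frozen=True)
class NoiseConfig:
    """Band-limited Gaussian torque noise, one independent channel per joint.

    ``target_std`` is the long-run standard deviation of each filtered
    channel in Nm; the white input is pre-scaled by the filter's noise
    power gain so realizations are unbiased rather than renormalized.
    """

    target_std: float = 2.844
    cutoff_hz: float = 10.0
    filter_order: int = 4
    seed: int = 0

    def __post_init__(self) -> None:
        if self.target_std < 0.0:
            raise ValueError("target_std must be non-negative")
        if self.cutoff_hz <= 0.0:
            raise ValueError("cutoff_hz must be positive")


def bias_torque(q_ref: JointState, p: AnthropometricParameters) -> np.ndarray:
    """Constant feed-forward torque cancelling gravity at the reference posture.

    Equals ``-gravity_torque(q_ref)``, so the reference is an exact
    equilibrium of the controlled dynamics; identically zero for the fully
    vertical reference.
    """
    return -gravity_torque(q_ref, p)


def stiffness_torque(
    q: JointState, sp: StiffnessParameters, q_ref: JointState
) -> np.ndarray:
    """Restoring visco-elastic torque -[K dq + B q̇] per joint, Nm."""
    return -np.array(
        [
            sp.K_a * (q.q1 - q_ref.q1) + sp.B_a * q.q1dot,
            sp.K_h * (q.q2 - q_ref.q2) + sp.B_h * q.q2dot,
        ]
    )


def vip_error(delayed: VIPState, q_com_ref: float = math.pi / 2) -> VIPError:
    """Delayed angular and angular-velocity error of the VIP."""
    return VIPError(dq=q_com_ref - delayed.q_com, dqdot=-delayed.q_com_dot)


def switch_active(e: VIPError, phi: float) -> bool:
    """Phase-plane switching rule: active iff dq*(dqdot + phi*dq) > 0.

    The rule selects the unsafe regions of the saddle's phase plane: the
    first/third quadrants of (dq, dqdot), widened by a slice of slope
    ``-phi`` cut from the second/fourth quadrants (``phi >= 0``; at
    ``phi = 0`` the active set is exactly the open quadrants).  Strict
    inequality: the boundary (including dq == 0) maps to "off".
    """
    return e.dq * (e.dqdot + phi * e.dq) > 0.0


def soft_clip(AS: float, sigma: float) -> float:
    """Cubic soft saturation of the ankle torque at threshold ``sigma``.

    ``AS - AS**3/(3 sigma**2)`` inside [-sigma, sigma], constant
    ``±2 sigma/3`` outside; odd, continuous, non-decreasing.
    """
    den = 3.0 * sigma**2
    if AS > sigma:
        return sigma - sigma**3 / den
    if AS < -sigma:
        return -sigma + sigma**3 / den
    return AS - AS**3 / den


def intermittent_torque(
    e: VIPError,
    gains: IntermittentGains,
    sat: Optional[SaturationParameters] = None,
) -> tuple[np.ndarray, bool]:
    """Delayed intermittent PD torque [AS, HS] and the shared switch flag.

    Both joints obey the single phase-plane switching rule; when inactive
    the torque is exactly zero.  Soft clipping, when configured, applies to
    the ankle channel only (the component transmitted to the ground).
    """
    active = switch_active(e, gains.phi)
    if not active:
        return np.zeros(2), False
    a_s = gains.P_a * e.dq + gains.D_a * e.dqdot
    h_s = gains.P_h * e.dq + gains.D_h * e.dqdot
    if sat is not None:
        a_s = soft_clip(a_s, sat.sigma)
    return np.array([a_s, h_s]), True


def _butter_lowpass(cfg: NoiseConfig, fs: float):
    nyquist = fs / 2.0
    if cfg.cutoff_hz >= nyquist:
        raise ValueError(
            f"cutoff {cfg.cutoff_hz} Hz must be below the Nyquist frequency {nyquist} Hz"
        )
    return signal.butter(cfg.filter_order, cfg.cutoff_hz, btype="low", fs=fs)


def noise_power_gain(cfg: NoiseConfig, fs: float, n_impulse: int = 1 << 14) -> float:
    """Std amplification sqrt(sum h^2) of the noise filter for white input."""
    b, a = _butter_lowpass(cfg, fs)
    impulse = np.zeros(n_impulse)
    impulse[0] = 1.0
    h = signal.lfilter(b, a, impulse)
    return float(np.sqrt(np.sum(h**2)))


def make_noise(n_samples: int, dt: float, cfg: NoiseConfig) -> np.ndarray:
    """Two independent low-pass-filtered Gaussian torque channels, shape (2, n).

    White Gaussian sequences are filtered causally (sample-by-sample
    recursion, zero initial state) by the configured Butterworth low-pass;
    the white input std is ``target_std`` divided by the filter's noise
    power gain, so each channel's long-run std equals ``target_std``.
    Reproducible from ``cfg.seed``; channel sub-streams are spawned from
    the seed so they stay independent.
    """
    if cfg.target_std == 0.0:
        return np.zeros((2, n_samples))
    fs = 1.0 / dt
    b, a = _butter_lowpass(cfg, fs)
    input_std = cfg.target_std / noise_power_gain(cfg, fs)
    children = np.random.SeedSequence(cfg.seed).spawn(2)
    out = np.empty((2, n_samples))
    for ch, ss in enumerate(children):
        white = np.random.default_rng(ss).standard_normal(n_samples) * input_std
        out[ch] = signal.lfilter(b, a, white)
    return out
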