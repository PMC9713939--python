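"""Time-stepping engine for the controlled DIP.

Forward Euler at a fixed step (1 ms by default), with:

* on-line reconstruction of the VIP angle from the joint angles and a
  backward-difference estimate of its angular velocity;
* a sensory delay realized by reading the stored VIP series exactly
  ``delay/dt`` samples behind the current step (during the first ``delay``
  seconds the delayed state is the initial state, i.e. the buffer is
  pre-filled, so a run started at rest has no artificial torque spike);
* early termination, flagged as a fall, when the VIP angle leaves a
  ±``fall_threshold`` band about vertical;
* bit-identical reproducibility from the master seed, which also seeds the
  two independent noise channels.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np
import pandas as pd

from . import _engine
from .control import (
    IntermittentGains,
    NoiseConfig,
    SaturationParameters,
    StiffnessParameters,
    bias_torque,
    make_noise,
)
from .dynamics import AnthropometricParameters, JointState

__all__ = [
    "SimulationConfig",
    "SimulationResult",
    "simulate",
    "vip_velocity_estimate",
    "classify_stability",
]

RAD2DEG = 180.0 / math.pi


@dataclass(frozen=True)
class SimulationConfig:
    """Full description of one run; defaults are the standard study conditions."""

    anthropometry: AnthropometricParameters = field(default_factory=AnthropometricParameters)
    stiffness: StiffnessParameters = field(default_factory=StiffnessParameters)
    gains: IntermittentGains = field(default_factory=IntermittentGains)
    noise: NoiseConfig = field(default_factory=NoiseConfig)
    saturation: Optional[SaturationParameters] = None
    dt: float = 0.001
    duration: float = 240.0
    delay: float = 0.2
    initial_state: JointState = field(default_factory=JointState.reference)
    reference_state: JointState = field(default_factory=JointState.reference)
    seed: int = 0
    fall_threshold: float = math.radians(30.0)
    transient_discard: float = 30.0

    def __post_init__(self) -> None:
        if self.dt <= 0.0 or self.duration <= 0.0:
            raise ValueError("dt and duration must be positive")
        ratio = self.delay / self.dt
        if abs(ratio - round(ratio)) > 1e-9:
            raise ValueError(
                f"delay ({self.delay} s) must be an integer multiple of dt ({self.dt} s)"
            )
        if self.duration <= self.transient_discard:
            raise ValueError("duration must exceed transient_discard")

    @property
    def delay_steps(self) -> int:
        return round(self.delay / self.dt)

    @property
    def n_steps(self) -> int:
        return round(self.duration / self.dt)


@dataclass
class SimulationResult:
    """Uniformly sampled trajectories, torque components and switch status.

    All angle series are radians; :meth:`to_frame` converts to degrees at
    the I/O boundary.  Torque arrays have shape ``(2, n)`` with row 0 the
    ankle channel and row 1 the hip channel.  ``fell_at`` is the time of
    early termination in seconds, or ``None`` for a completed run.
    """

    config: Optional[SimulationConfig]
    t: np.ndarray
    q1: np.ndarray
    q2: np.ndarray
    q1dot: np.ndarray
    q2dot: np.ndarray
    q1ddot: np.ndarray
    q2ddot: np.ndarray
    q_com: np.ndarray
    q_com_dot: np.ndarray
    tau_gravity: np.ndarray
    tau_stiffness: np.ndarray
    tau_intermittent: np.ndarray
    tau_noise: np.ndarray
    switch: np.ndarray
    fell_at: Optional[float] = None

    @property
    def completed(self) -> bool:
        return self.fell_at is None

    @property
    def dt(self) -> float:
        if self.config is not None:
            return self.config.dt
        return float(self.t[1] - self.t[0])

    def post_transient(self, discard_s: Optional[float] = None) -> slice:
        """Index slice of the record after the settling transient."""
        if discard_s is None:
            discard_s = self.config.transient_discard if self.config is not None else 30.0
        return slice(int(round(discard_s / self.dt)), len(self.t))

    def to_frame(self) -> pd.DataFrame:
        """Time-series table, degrees and Nm at the boundary."""
        return pd.DataFrame(
            {
                "t_s": self.t,
                "q1_deg": self.q1 * RAD2DEG,
                "q2_deg": self.q2 * RAD2DEG,
                "qcom_deg": self.q_com * RAD2DEG,
                "q1dot_deg_s": self.q1dot * RAD2DEG,
                "q2dot_deg_s": self.q2dot * RAD2DEG,
                "qcomdot_deg_s": self.q_com_dot * RAD2DEG,
                "q1ddot_deg_s2": self.q1ddot * RAD2DEG,
                "q2ddot_deg_s2": self.q2ddot * RAD2DEG,
                "tau_grav_ankle_nm": self.tau_gravity[0],
                "tau_grav_hip_nm": self.tau_gravity[1],
                "tau_stiff_ankle_nm": self.tau_stiffness[0],
                "tau_stiff_hip_nm": self.tau_stiffness[1],
                "tau_int_ankle_nm": self.tau_intermittent[0],
                "tau_int_hip_nm": self.tau_intermittent[1],
                "tau_noise_ankle_nm": self.tau_noise[0],
                "tau_noise_hip_nm": self.tau_noise[1],
                "switch": self.switch.astype(int),
            }
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "SimulationResult":
        """Rebuild a result from a :meth:`to_frame` table (config-less)."""
        d = math.pi / 180.0
        return cls(
            config=None,
            t=frame["t_s"].to_numpy(),
            q1=frame["q1_deg"].to_numpy() * d,
            q2=frame["q2_deg"].to_numpy() * d,
            q1dot=frame["q1dot_deg_s"].to_numpy() * d,
            q2dot=frame["q2dot_deg_s"].to_numpy() * d,
            q1ddot=frame["q1ddot_deg_s2"].to_numpy() * d,
            q2ddot=frame["q2ddot_deg_s2"].to_numpy() * d,
            q_com=frame["qcom_deg"].to_numpy() * d,
            q_com_dot=frame["qcomdot_deg_s"].to_numpy() * d,
            tau_gravity=np.vstack(
                [frame["tau_grav_ankle_nm"].to_numpy(), frame["tau_grav_hip_nm"].to_numpy()]
            ),
            tau_stiffness=np.vstack(
                [frame["tau_stiff_ankle_nm"].to_numpy(), frame["tau_stiff_hip_nm"].to_numpy()]
            ),
            tau_intermittent=np.vstack(
                [frame["tau_int_ankle_nm"].to_numpy(), frame["tau_int_hip_nm"].to_numpy()]
            ),
            tau_noise=np.vstack(
                [frame["tau_noise_ankle_nm"].to_numpy(), frame["tau_noise_hip_nm"].to_numpy()]
            ),
            switch=frame["switch"].to_numpy().astype(bool),
        )


def simulate(cfg: SimulationConfig) -> SimulationResult:
    """Run one forward-Euler simulation of the controlled DIP.

    Early termination on a fall is a normal outcome (``result.fell_at`` is
    set and the series are truncated at the offending sample).  Identical
    configurations and seeds give bit-identical arrays.
    """
    p = cfg.anthropometry
    n = cfg.n_steps
    noise = make_noise(n, cfg.dt, replace(cfg.noise, seed=cfg.seed))
    tau_b = bias_torque(cfg.reference_state, p)
    w1 = p.m1 * p.r1 + p.m2 * p.L1
    w2 = p.m2 * p.r2
    sigma = cfg.saturation.sigma if cfg.saturation is not None else -1.0
    ref_vip = math.pi / 2 if cfg.reference_state.q1 == math.pi / 2 else None
    if ref_vip is None:
        # General tilted reference: VIP reference is the CoM angle there.
        from .dynamics import com_and_vip

        ref_vip = com_and_vip(cfg.reference_state, p).q_com

    out = _engine.step_loop(
        n,
        cfg.dt,
        cfg.delay_steps,
        p.A,
        p.B,
        p.D,
        w1,
        w2,
        p.g,
        cfg.stiffness.K_a,
        cfg.stiffness.B_a,
        cfg.stiffness.K_h,
        cfg.stiffness.B_h,
        cfg.reference_state.q1,
        cfg.reference_state.q2,
        cfg.gains.P_a,
        cfg.gains.D_a,
        cfg.gains.P_h,
        cfg.gains.D_h,
        cfg.gains.phi,
        sigma,
        tau_b[0],
        tau_b[1],
        noise[0],
        noise[1],
        cfg.initial_state.q1,
        cfg.initial_state.q2,
        cfg.initial_state.q1dot,
        cfg.initial_state.q2dot,
        ref_vip,
        cfg.fall_threshold,
    )
    (q1, q2, q1dot, q2dot, q1ddot, q2ddot, q_com, q_com_dot,
     tau_grav, tau_stiff, tau_int, switch, fell_at) = out

    n_used = n if fell_at < 0 else fell_at + 1
    sl = slice(0, n_used)
    return SimulationResult(
        config=cfg,
        t=np.arange(n_used) * cfg.dt,
        q1=q1[sl],
        q2=q2[sl],
        q1dot=q1dot[sl],
        q2dot=q2dot[sl],
        q1ddot=q1ddot[sl],
        q2ddot=q2ddot[sl],
        q_com=q_com[sl],
        q_com_dot=q_com_dot[sl],
        tau_gravity=tau_grav[:, sl],
        tau_stiffness=tau_stiff[:, sl],
        tau_intermittent=tau_int[:, sl],
        tau_noise=noise[:, sl],
        switch=switch[sl].astype(bool),
        fell_at=None if fell_at < 0 else fell_at * cfg.dt,
    )


def vip_velocity_estimate(q_com: np.ndarray, dt: float) -> np.ndarray:
    """Backward-difference angular velocity of the VIP angle series.

    The first sample's velocity is defined as zero.
    """
    q_com = np.asarray(q_com, dtype=float)
    if q_com.size < 2:
        raise ValueError("need at least 2 samples")
    out = np.empty_like(q_com)
    out[0] = 0.0
    out[1:] = np.diff(q_com) / dt
    return out


def classify_stability(
    result: SimulationResult,
    bounded_threshold: float = math.radians(10.0),
    discard_s: Optional[float] = None,
) -> str:
    """Label a run ``"stable"`` or ``"unstable"``.

    Unstable iff the run fell, or the post-transient VIP excursion from
    vertical exceeds ``bounded_threshold`` (rad).  Sway in stable runs is
    well under 1 degree, so the label is insensitive to the exact cut.
    """
    if not result.completed:
        return "unstable"
    sl = result.post_transient(discard_s)
    if np.max(np.abs(result.q_com[sl] - math.pi / 2)) > bounded_threshold:
        return "unstable"
    return "stable"
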