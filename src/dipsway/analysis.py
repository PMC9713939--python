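"""Derived sway indicators and parameter-space experiments.

Summary statistics of a single run (standard deviations, off-time,
controller power, ankle-hip acceleration regression) plus the three
multi-run protocols: per-axis range-of-variation (RoV) scans of the
intermittent gains, the hip-stiffness-multiple (mu_h) sensitivity sweep,
and the ankle-torque saturation experiment.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .control import SaturationParameters, StiffnessParameters
from .simulator import (
    RAD2DEG,
    SimulationConfig,
    SimulationResult,
    classify_stability,
    simulate,
)

__all__ = [
    "SwaySummary",
    "RoVResult",
    "sway_statistics",
    "mean_intermittent_power",
    "off_time_fraction",
    "antiphase_regression",
    "rov_scan",
    "mu_h_sweep",
    "saturation_experiment",
]


@dataclass(frozen=True)
class SwaySummary:
    """Single-run sway indicators over the post-transient record.

    Angle standard deviations are degrees; torque standard deviations Nm;
    powers W. Torque and power fields carry both joint channels
    (``*_ankle`` / ``*_hip``); powers come in the signed time-average and
    the magnitude (absolute) time-average, the latter being the headline
    indicator since a signed mean can vanish by cancellation.
    """

    std_qcom: float
    std_q1: float
    std_q2: float
    std_tau_gravity_ankle: float
    std_tau_gravity_hip: float
    std_tau_stiffness_ankle: float
    std_tau_stiffness_hip: float
    std_tau_intermittent_ankle: float
    std_tau_intermittent_hip: float
    std_tau_noise_ankle: float
    std_tau_noise_hip: float
    mean_power_ankle: float
    mean_power_hip: float
    mean_abs_power_ankle: float
    mean_abs_power_hip: float
    off_time_fraction: float
    slope_hip_on_ankle: float
    slope_ankle_on_hip: float
    pearson_r: float

    def to_dict(self) -> dict:
        return {k: float(v) for k, v in self.__dict__.items()}


@dataclass(frozen=True)
class RoVResult:
    """Stable interval of one scanned gain, holding the others at base values.

    ``lower``/``upper`` are the extreme stable grid points of the
    contiguous stable interval containing the base value; ``grid`` and
    ``stable`` record the scan; ``seeds`` the noise seeds used per point.
    """

    axis: str
    lower: float
    upper: float
    grid: np.ndarray
    stable: np.ndarray
    seeds: tuple[int, ...]

    @property
    def width(self) -> float:
        return self.upper - self.lower


def _require_completed(result: SimulationResult) -> None:
    if not result.completed:
        raise ValueError(f"run fell at t = {result.fell_at:.3f} s; statistics undefined")


def sway_statistics(
    result: SimulationResult, discard_s: Optional[float] = None
) -> SwaySummary:
    """Table of sway indicators for a completed run.

    Raises ``ValueError`` for a fallen run.  All statistics are computed
    over the record after the settling transient (``discard_s`` seconds,
    defaulting to the run configuration's value).
    """
    _require_completed(result)
    sl = result.post_transient(discard_s)
    p_ankle = result.tau_intermittent[0, sl] * result.q1dot[sl]
    p_hip = result.tau_intermittent[1, sl] * result.q2dot[sl]
    slope_h, slope_a, r = _regress(result.q1ddot[sl], result.q2ddot[sl])
    return SwaySummary(
        std_qcom=float(np.std(result.q_com[sl])) * RAD2DEG,
        std_q1=float(np.std(result.q1[sl])) * RAD2DEG,
        std_q2=float(np.std(result.q2[sl])) * RAD2DEG,
        std_tau_gravity_ankle=float(np.std(result.tau_gravity[0, sl])),
        std_tau_gravity_hip=float(np.std(result.tau_gravity[1, sl])),
        std_tau_stiffness_ankle=float(np.std(result.tau_stiffness[0, sl])),
        std_tau_stiffness_hip=float(np.std(result.tau_stiffness[1, sl])),
        std_tau_intermittent_ankle=float(np.std(result.tau_intermittent[0, sl])),
        std_tau_intermittent_hip=float(np.std(result.tau_intermittent[1, sl])),
        std_tau_noise_ankle=float(np.std(result.tau_noise[0, sl])),
        std_tau_noise_hip=float(np.std(result.tau_noise[1, sl])),
        mean_power_ankle=float(np.mean(p_ankle)),
        mean_power_hip=float(np.mean(p_hip)),
        mean_abs_power_ankle=float(np.mean(np.abs(p_ankle))),
        mean_abs_power_hip=float(np.mean(np.abs(p_hip))),
        off_time_fraction=off_time_fraction(result, discard_s),
        slope_hip_on_ankle=slope_h,
        slope_ankle_on_hip=slope_a,
        pearson_r=r,
    )


def mean_intermittent_power(
    result: SimulationResult, discard_s: Optional[float] = None, signed: bool = False
) -> tuple[float, float]:
    """Time-averaged intermittent controller power (ankle W, hip W).

    Each joint's intermittent torque is multiplied sample-wise by that
    joint's angular velocity and averaged over the post-transient record.
    By default the magnitude ``mean(|tau * qdot|)`` is returned; pass
    ``signed=True`` for the signed net power, which can be near zero by
    cancellation between concentric and eccentric phases.
    """
    _require_completed(result)
    sl = result.post_transient(discard_s)
    p_a = result.tau_intermittent[0, sl] * result.q1dot[sl]
    p_h = result.tau_intermittent[1, sl] * result.q2dot[sl]
    if signed:
        return float(np.mean(p_a)), float(np.mean(p_h))
    return float(np.mean(np.abs(p_a))), float(np.mean(np.abs(p_h)))


def off_time_fraction(
    result: SimulationResult, discard_s: Optional[float] = None
) -> float:
    """Fraction of post-transient samples with the switch off."""
    _require_completed(result)
    sl = result.post_transient(discard_s)
    return float(1.0 - np.mean(result.switch[sl]))


def _regress(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """OLS slopes y-on-x and x-on-y plus the Pearson correlation."""
    cov = float(np.cov(x, y)[0, 1])
    vx, vy = float(np.var(x, ddof=1)), float(np.var(y, ddof=1))
    r = cov / math.sqrt(vx * vy) if vx > 0 and vy > 0 else float("nan")
    return cov / vx if vx > 0 else float("nan"), cov / vy if vy > 0 else float("nan"), r


def antiphase_regression(
    result: SimulationResult, discard_s: Optional[float] = None
) -> dict:
    """Ankle-hip angular-acceleration regression over the post-transient record.

    Returns the OLS slopes in both orientations, the Pearson correlation,
    and ``slope_steeper``: the orientation whose slope magnitude exceeds
    unity (at most one can), the headline anti-phase indicator.
    """
    _require_completed(result)
    sl = result.post_transient(discard_s)
    slope_h, slope_a, r = _regress(result.q1ddot[sl], result.q2ddot[sl])
    # The two slopes multiply to r^2 <= 1, so at most one magnitude exceeds unity.
    steeper = slope_h if abs(slope_h) > abs(slope_a) else slope_a
    return {
        "slope_hip_on_ankle": slope_h,
        "slope_ankle_on_hip": slope_a,
        "pearson_r": r,
        "slope_steeper": steeper,
    }


def _stable_majority(cfg: SimulationConfig, seeds: Sequence[int]) -> bool:
    votes = [classify_stability(simulate(replace(cfg, seed=s))) == "stable" for s in seeds]
    return sum(votes) * 2 > len(votes)


def rov_scan(
    base_config: SimulationConfig,
    axis: str,
    grid: Sequence[float],
    seeds: Sequence[int] = (0, 1, 2),
) -> RoVResult:
    """Stable interval of one intermittent gain along a scan grid.

    ``axis`` is one of ``"P_a"``, ``"D_a"``, ``"P_h"``, ``"D_h"``; the
    other gains stay at their base values.  A grid point is stable when a
    majority of the seeds yields a stable run; the reported interval is
    the contiguous stable block containing the grid point nearest the base
    value.  Raises ``ValueError`` if that point is unstable.
    """
    if axis not in ("P_a", "D_a", "P_h", "D_h"):
        raise ValueError(f"unknown gain axis {axis!r}")
    grid = np.asarray(sorted(grid), dtype=float)
    stable = np.zeros(len(grid), dtype=bool)
    for i, val in enumerate(grid):
        cfg = replace(base_config, gains=replace(base_config.gains, **{axis: float(val)}))
        stable[i] = _stable_majority(cfg, seeds)
    base_val = getattr(base_config.gains, axis)
    i0 = int(np.argmin(np.abs(grid - base_val)))
    if not stable[i0]:
        raise ValueError(f"base point {axis}={base_val} is unstable on the scan grid")
    lo = i0
    while lo > 0 and stable[lo - 1]:
        lo -= 1
    hi = i0
    while hi < len(grid) - 1 and stable[hi + 1]:
        hi += 1
    return RoVResult(
        axis=axis,
        lower=float(grid[lo]),
        upper=float(grid[hi]),
        grid=grid,
        stable=stable,
        seeds=tuple(int(s) for s in seeds),
    )


def mu_h_sweep(
    base_config: SimulationConfig,
    mu_values: Sequence[float],
    seeds: Sequence[int] = (0, 1, 2),
) -> pd.DataFrame:
    """Re-run the base strategy at each hip-stiffness multiple ``mu_h``.

    Sets ``K_h = mu_h * K_h_crit`` (other stiffness parameters unchanged)
    and reports, per value: the majority stability label, the across-seed
    mean ``std(q_com)`` (deg) and steeper regression slope over the stable
    seeds (NaN if none).
    """
    p = base_config.anthropometry
    rows = []
    for mu in mu_values:
        st = replace(
            base_config.stiffness, K_h=mu * p.critical_hip_stiffness, mu_h=float(mu)
        )
        cfg = replace(base_config, stiffness=st)
        stds, slopes, n_stable = [], [], 0
        for s in seeds:
            res = simulate(replace(cfg, seed=s))
            if classify_stability(res) == "stable":
                n_stable += 1
                stds.append(sway_statistics(res).std_qcom)
                slopes.append(antiphase_regression(res)["slope_steeper"])
        rows.append(
            {
                "mu_h": float(mu),
                "stability": "stable" if n_stable * 2 > len(seeds) else "unstable",
                "n_stable": n_stable,
                "n_seeds": len(seeds),
                "std_qcom_deg": float(np.mean(stds)) if stds else float("nan"),
                "slope_steeper": float(np.mean(slopes)) if slopes else float("nan"),
            }
        )
    return pd.DataFrame(rows)


def saturation_experiment(
    base_config: SimulationConfig,
    sigma_values: Sequence[Optional[float]],
    seeds: Sequence[int] = (0, 1, 2, 3, 4),
) -> pd.DataFrame:
    """Soft-clip the ankle intermittent torque at each threshold ``sigma``.

    ``None`` in ``sigma_values`` means no clipping.  Reports the majority
    stability label and the across-seed mean std of the ankle intermittent
    torque over stable seeds (NaN if none).
    """
    rows = []
    for sigma in sigma_values:
        sat = None if sigma is None else SaturationParameters(sigma=float(sigma))
        cfg = replace(base_config, saturation=sat)
        stds, n_stable = [], 0
        for s in seeds:
            res = simulate(replace(cfg, seed=s))
            if classify_stability(res) == "stable":
                n_stable += 1
                stds.append(sway_statistics(res).std_tau_intermittent_ankle)
        rows.append(
            {
                "sigma_nm": float("nan") if sigma is None else float(sigma),
                "stability": "stable" if n_stable * 2 > len(seeds) else "unstable",
                "n_stable": n_stable,
                "n_seeds": len(seeds),
                "std_tau_int_ankle_nm": float(np.mean(stds)) if stds else float("nan"),
            }
        )
    return pd.DataFrame(rows)
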