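"""Run-configuration parsing, validation and provenance hashing.

Configurations are YAML files with nested sections mirroring the library
objects; every field is optional and defaults to the standard study
conditions (young-adult-male anthropometrics, printed passive constants,
mid-range pure ankle strategy).  Key names carry unit suffixes (``_kg``,
``_m``, ``_s``, ``_deg``, ``_nm_per_rad``, ``_nms_per_rad``, ``_nm``,
``_hz``); unknown keys are rejected with a field-path message.  Angles are
degrees at this boundary and converted to radians internally.
"""

from __future__ import annotations

import hashlib
import json
import math
from pathlib import Path
from typing import Any, Mapping, Optional, Union

import yaml

from .control import (
    IntermittentGains,
    NoiseConfig,
    SaturationParameters,
    StiffnessParameters,
)
from .dynamics import AnthropometricParameters, JointState
from .simulator import SimulationConfig

__all__ = ["load_config", "config_from_dict", "config_hash"]


class ConfigError(ValueError):
    """Schema violation in a run configuration."""


_SCHEMA: dict[str, dict[str, str]] = {
    "anthropometry": {
        "m1_kg": "m1",
        "m2_kg": "m2",
        "L1_m": "L1",
        "L2_m": "L2",
        "r1_m": "r1",
        "r2_m": "r2",
        "g_m_s2": "g",
        "critical_ankle_stiffness_nm_per_rad": "critical_ankle_stiffness",
    },
    "stiffness": {
        "K_a_nm_per_rad": "K_a",
        "B_a_nms_per_rad": "B_a",
        "K_h_nm_per_rad": "K_h",
        "B_h_nms_per_rad": "B_h",
        "mu_h": "mu_h",
    },
    "gains": {
        "P_a_nm_per_rad": "P_a",
        "D_a_nms_per_rad": "D_a",
        "P_h_nm_per_rad": "P_h",
        "D_h_nms_per_rad": "D_h",
        "phi": "phi",
    },
    "noise": {
        "target_std_nm": "target_std",
        "cutoff_hz": "cutoff_hz",
        "filter_order": "filter_order",
    },
    "saturation": {"sigma_nm": "sigma"},
    "simulation": {
        "dt_s": "dt",
        "duration_s": "duration",
        "delay_s": "delay",
        "seed": "seed",
        "fall_threshold_deg": "fall_threshold_deg",
        "transient_discard_s": "transient_discard",
        "initial_q1_deg": "initial_q1_deg",
        "initial_q2_deg": "initial_q2_deg",
        "initial_q1dot_deg_s": "initial_q1dot_deg_s",
        "initial_q2dot_deg_s": "initial_q2dot_deg_s",
    },
}


def _check_section(name: str, raw: Mapping[str, Any]) -> dict[str, Any]:
    if not isinstance(raw, Mapping):
        raise ConfigError(f"section '{name}' must be a mapping, got {type(raw).__name__}")
    allowed = _SCHEMA[name]
    out: dict[str, Any] = {}
    for key, val in raw.items():
        if key not in allowed:
            raise ConfigError(
                f"unknown key '{name}.{key}' (allowed: {', '.join(sorted(allowed))})"
            )
        out[allowed[key]] = val
    return out


def config_from_dict(raw: Optional[Mapping[str, Any]]) -> SimulationConfig:
    """Build a fully defaulted, validated :class:`SimulationConfig`.

    An empty/absent mapping yields the default study conditions (pure
    ankle strategy, P_a = 875 Nm/rad, D_a = 125 Nms/rad).
    """
    raw = dict(raw or {})
    unknown = set(raw) - set(_SCHEMA)
    if unknown:
        raise ConfigError(
            f"unknown section(s) {sorted(unknown)} (allowed: {sorted(_SCHEMA)})"
        )
    sections = {name: _check_section(name, raw.get(name) or {}) for name in _SCHEMA}

    try:
        anthro = AnthropometricParameters(**sections["anthropometry"])
        stiff_kw = sections["stiffness"]
        mu_h = stiff_kw.pop("mu_h", None)
        if mu_h is not None and "K_h" not in stiff_kw:
            stiffness = StiffnessParameters.from_mu_h(mu_h, anthro, **stiff_kw)
        else:
            stiffness = StiffnessParameters(mu_h=mu_h, **stiff_kw)
        gains = IntermittentGains(**sections["gains"])
        noise = NoiseConfig(**sections["noise"])
        sigma = sections["saturation"].get("sigma")
        saturation = None if sigma is None else SaturationParameters(sigma=float(sigma))

        sim = dict(sections["simulation"])
        fall_deg = sim.pop("fall_threshold_deg", 30.0)
        q1_deg = sim.pop("initial_q1_deg", 90.0)
        q2_deg = sim.pop("initial_q2_deg", 0.0)
        q1d = sim.pop("initial_q1dot_deg_s", 0.0)
        q2d = sim.pop("initial_q2dot_deg_s", 0.0)
        initial = JointState(
            q1=math.radians(q1_deg),
            q2=math.radians(q2_deg),
            q1dot=math.radians(q1d),
            q2dot=math.radians(q2d),
        )
        return SimulationConfig(
            anthropometry=anthro,
            stiffness=stiffness,
            gains=gains,
            noise=noise,
            saturation=saturation,
            initial_state=initial,
            fall_threshold=math.radians(fall_deg),
            **sim,
        )
    except (TypeError, ValueError) as exc:
        if isinstance(exc, ConfigError):
            raise
        raise ConfigError(str(exc)) from exc


def load_config(path: Union[str, Path]) -> SimulationConfig:
    """Load and validate a YAML run configuration file.

    An empty file yields the full default configuration.  Raises
    ``FileNotFoundError`` for a missing file and :class:`ConfigError` with
    a field-path message for schema violations.
    """
    path = Path(path)
    raw = yaml.safe_load(path.read_text())
    if raw is not None and not isinstance(raw, Mapping):
        raise ConfigError(f"top level of {path} must be a mapping")
    return config_from_dict(raw)


def _canonical(obj: Any) -> Any:
    if hasattr(obj, "__dataclass_fields__"):
        return {k: _canonical(getattr(obj, k)) for k in sorted(obj.__dataclass_fields__)}
    if isinstance(obj, (list, tuple)):
        return [_canonical(v) for v in obj]
    return obj


def config_hash(cfg: SimulationConfig) -> str:
    """Deterministic hex digest of a configuration, for provenance blocks."""
    payload = json.dumps(_canonical(cfg), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()[:16]
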