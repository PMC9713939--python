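"""Deterministic short canned runs and constructed series for tests.

The fixture set contains 5-second simulations of each pure strategy, an
exactly anti-phase acceleration pair (slope -3 by construction) and a
zero-noise equilibrium run; all files are byte-identical across re-runs
with the same seed.
"""

from __future__ import annotations

from dataclasses import replace
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from .control import IntermittentGains, NoiseConfig
from .simulator import SimulationConfig, simulate

__all__ = ["generate_fixtures"]

_FLOAT_FMT = "%.10g"


def _short_config(seed: int, **gains) -> SimulationConfig:
    return SimulationConfig(
        seed=seed,
        duration=5.0,
        transient_discard=1.0,
        gains=IntermittentGains(**gains) if gains else IntermittentGains(),
    )


def generate_fixtures(out_dir: Union[str, Path], seed: int = 0) -> list[Path]:
    """Write the fixture CSVs into ``out_dir`` and return their paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []

    runs = {
        "ankle_short": _short_config(seed),
        "hip_short": _short_config(seed + 1, P_a=0.0, D_a=0.0, P_h=1120.0, D_h=305.0),
        "equilibrium": replace(_short_config(seed), noise=NoiseConfig(target_std=0.0)),
    }
    for name, cfg in runs.items():
        path = out / f"{name}.csv"
        simulate(cfg).to_frame().to_csv(path, index=False, float_format=_FLOAT_FMT)
        written.append(path)

    rng = np.random.default_rng(seed)
    acc1 = rng.standard_normal(2000)
    pd.DataFrame({"q1ddot": acc1, "q2ddot": -3.0 * acc1}).to_csv(
        out / "antiphase_exact.csv", index=False, float_format=_FLOAT_FMT
    )
    written.append(out / "antiphase_exact.csv")
    return written
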