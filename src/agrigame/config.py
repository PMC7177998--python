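"""Plain-text run configuration and trajectory I/O.

A run config is a flat YAML mapping of parameter symbols to numbers plus a
handful of run controls:

    Sg: 0.85
    ...
    alpha: 0.5
    x0: 0.4      # initial shares (default 0.4, 0.2, 0.3)
    y0: 0.2
    z0: 0.3
    t_end: 300   # integration settings (defaults as in IntegrationSettings)
    seed: 1      # optional, for sampling utilities

Unknown keys are rejected by name.  Trajectories are exported as CSV with
header ``t,x,y,z`` at full floating precision, so a read-back round-trips
exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import IntegrationSettings, Trajectory
from .errors import ConfigError, ParameterError
from .model import GameParameters, MixedState, validate

__all__ = ["RunConfig", "read_config", "write_config", "write_trajectory", "read_trajectory"]

_SETTING_KEYS = ("t_end", "rel_tol", "abs_tol", "max_step", "clamp_tol")
_STATE_KEYS = ("x0", "y0", "z0")
_MISC_KEYS = ("seed", "out")


@dataclass(frozen=True)
class RunConfig:
    params: GameParameters
    initial: MixedState = field(default_factory=lambda: MixedState(0.4, 0.2, 0.3))
    settings: IntegrationSettings = field(default_factory=IntegrationSettings)
    seed: int | None = None
    out: str | None = None

    def to_dict(self) -> dict:
        data = dict(self.params.to_dict(include_complements=True))
        data.update(x0=self.initial.x, y0=self.initial.y, z0=self.initial.z)
        defaults = IntegrationSettings()
        for key in _SETTING_KEYS:
            value = getattr(self.settings, key)
            if value != getattr(defaults, key):
                data[key] = value
        if self.seed is not None:
            data["seed"] = self.seed
        if self.out is not None:
            data["out"] = self.out
        return data


def read_config(path: str | Path) -> RunConfig:
    """Parse and fully validate a flat YAML run configuration."""
    path = Path(path)
    try:
        raw = yaml.safe_load(path.read_text())
    except yaml.YAMLError as exc:
        raise ConfigError(f"could not parse {path}: {exc}") from exc
    if not isinstance(raw, dict):
        raise ConfigError(f"{path} must contain a flat key: value mapping")

    extras = {k: raw.pop(k) for k in (*_STATE_KEYS, *_SETTING_KEYS, *_MISC_KEYS) if k in raw}
    try:
        params = GameParameters.from_dict(raw)
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    report = validate(params)
    if not report.is_valid:
        raise ConfigError("; ".join(report.hard_violations))

    try:
        initial = MixedState(
            float(extras.get("x0", 0.4)),
            float(extras.get("y0", 0.2)),
            float(extras.get("z0", 0.3)),
        )
    except ParameterError as exc:
        raise ConfigError(str(exc)) from exc
    setting_kwargs = {k: extras[k] for k in _SETTING_KEYS if k in extras}
    if "max_step" in setting_kwargs and setting_kwargs["max_step"] is not None:
        setting_kwargs["max_step"] = float(setting_kwargs["max_step"])
    settings = IntegrationSettings(**setting_kwargs)
    seed = extras.get("seed")
    return RunConfig(
        params=params,
        initial=initial,
        settings=settings,
        seed=None if seed is None else int(seed),
        out=extras.get("out"),
    )


def write_config(config: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(config.to_dict(), sort_keys=False))


def write_trajectory(traj: Trajectory, path: str | Path) -> None:
    """CSV export ``t,x,y,z``, one row per stored time point, full precision."""
    if len(traj) == 0:
        raise ConfigError("refusing to write an empty trajectory")
    traj.to_frame().to_csv(path, index=False, float_format="%.17g")


def read_trajectory(path: str | Path, params: GameParameters) -> Trajectory:
    df = pd.read_csv(path, float_precision="round_trip")
    expected = ["t", "x", "y", "z"]
    if list(df.columns) != expected:
        raise ConfigError(f"trajectory file must have columns {expected}, got {list(df.columns)}")
    return Trajectory(
        times=df["t"].to_numpy(),
        states=df[["x", "y", "z"]].to_numpy(),
        params=params,
    )
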