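"""Named simulation scenarios and comparative-dynamics sweeps.

The study conditions: all presets share one benchmark parameter set
(Sg=0.85, Se=0.7, Sh=0.4, Pg=0.2, Dh=0.1, Cg=0.1, Pe=0.2, We=0.1, Le=0.25,
Ce=0.3, kebe=0.1, dSe=0.25, dSh=0.25, Ch=0.25, khbh=0.05, Wh=0.1, dWh=0.05,
dSg=0.5, alpha=0.5) and the initial shares (0.4, 0.2, 0.3), varying one
policy lever each:

* ``baseline_prop1``     — benchmark; full cooperation (E8) is stable.
* ``prop2_low_reward``   — superior-government reward cut to dSg=0.01;
                           governments drop out, the system settles at E7.
* ``prop3_high_cost``    — green-production costs raised to Ce=0.9, Ch=0.8;
                           producers defect, the system settles at E4.
* ``prop4_alpha_high`` / ``prop4_alpha_low`` — operator land share 0.8 / 0.1;
                           the limit is unchanged (E8) but farmers converge
                           slower the more land is transferred.
* ``prop5_synergy``      — mixed start (0.8, 0.5, 0.1) with dSe=0.3; base for
                           the green-synergy parameter sweeps.

Slow presets integrate to t_end=2000 so that limits, not timings, are the
claim being checked.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import equilibria
from .dynamics import (
    ConvergenceResult,
    IntegrationSettings,
    Trajectory,
    first_passage_time,
    integrate,
    limit_state,
)
from .errors import AgrigameError, ParameterError
from .model import GameParameters, MixedState, require_valid

__all__ = [
    "Scenario",
    "ScenarioReport",
    "SweepReport",
    "BASELINE_PARAMETERS",
    "preset",
    "preset_names",
    "run_scenario",
    "sweep",
]

BASELINE_PARAMETERS = GameParameters(
    Sg=0.85, Se=0.7, Sh=0.4, Pg=0.2, Dh=0.1, Cg=0.1,
    Pe=0.2, We=0.1, Le=0.25, Ce=0.3, kebe=0.1, dSe=0.25,
    dSh=0.25, Ch=0.25, khbh=0.05, Wh=0.1, dWh=0.05, dSg=0.5, alpha=0.5,
)

_BASELINE_INITIAL = MixedState(0.4, 0.2, 0.3)

#: Default threshold above which a population counts as "cooperating".
COOPERATION_THRESHOLD = 0.99


@dataclass(frozen=True)
class Scenario:
    name: str
    params: GameParameters
    initial: MixedState
    settings: IntegrationSettings = field(default_factory=IntegrationSettings)
    expected_limit: str | None = None  # vertex label E1..E8

    def __post_init__(self) -> None:
        require_valid(self.params)


@dataclass(frozen=True)
class ScenarioReport:
    scenario: Scenario
    trajectory: Trajectory
    convergence: ConvergenceResult
    conditions: set[int]
    stability: pd.DataFrame
    first_passage: dict[str, float | None]
    limit_matches_expected: bool | None  # None when no expected limit declared
    mismatch: str | None


_PRESETS: dict[str, Scenario] = {
    "baseline_prop1": Scenario(
        name="baseline_prop1",
        params=BASELINE_PARAMETERS,
        initial=_BASELINE_INITIAL,
        settings=IntegrationSettings(t_end=300.0),
        expected_limit="E8",
    ),
    "prop2_low_reward": Scenario(
        name="prop2_low_reward",
        params=BASELINE_PARAMETERS.replace(dSg=0.01),
        initial=_BASELINE_INITIAL,
        settings=IntegrationSettings(t_end=2000.0),
        expected_limit="E7",
    ),
    "prop3_high_cost": Scenario(
        name="prop3_high_cost",
        params=BASELINE_PARAMETERS.replace(Ce=0.9, Ch=0.8),
        initial=_BASELINE_INITIAL,
        settings=IntegrationSettings(t_end=1000.0),
        expected_limit="E4",
    ),
    "prop4_alpha_high": Scenario(
        name="prop4_alpha_high",
        params=BASELINE_PARAMETERS.replace(alpha=0.8),
        initial=_BASELINE_INITIAL,
        settings=IntegrationSettings(t_end=2000.0),
        expected_limit="E8",
    ),
    "prop4_alpha_low": Scenario(
        name="prop4_alpha_low",
        params=BASELINE_PARAMETERS.replace(alpha=0.1),
        initial=_BASELINE_INITIAL,
        settings=IntegrationSettings(t_end=2000.0),
        expected_limit="E8",
    ),
    "prop5_synergy": Scenario(
        name="prop5_synergy",
        params=BASELINE_PARAMETERS.replace(dSe=0.3),
        initial=MixedState(0.8, 0.5, 0.1),
        settings=IntegrationSettings(t_end=300.0),
        expected_limit=None,
    ),
}


def preset_names() -> list[str]:
    return list(_PRESETS)


def preset(name: str) -> Scenario:
    """Look up a named scenario; unknown names list the available presets."""
    try:
        return _PRESETS[name]
    except KeyError:
        raise AgrigameError(
            f"unknown preset {name!r}; available: {', '.join(_PRESETS)}"
        ) from None


def run_scenario(
    scenario: Scenario, cooperation_threshold: float = COOPERATION_THRESHOLD
) -> ScenarioReport:
    """Integrate a scenario and assemble its full diagnostic report.

    A declared expected limit that the trajectory does not reach is recorded
    as a mismatch in the report, not raised.
    """
    traj = integrate(scenario.params, scenario.initial, scenario.settings)
    conv = limit_state(traj)
    conditions = equilibria.check_conditions(scenario.params)
    stability = equilibria.stability_report(scenario.params)
    fp = {
        c: first_passage_time(traj, c, cooperation_threshold) for c in ("x", "y", "z")
    }
    matches: bool | None = None
    mismatch: str | None = None
    if scenario.expected_limit is not None:
        matches = conv.converged and conv.matched_vertex == scenario.expected_limit
        if not matches:
            mismatch = (
                f"expected limit {scenario.expected_limit}, got "
                f"{conv.matched_vertex or 'no vertex'} "
                f"(converged={conv.converged}, residual={conv.residual:.3e})"
            )
    return ScenarioReport(
        scenario=scenario,
        trajectory=traj,
        convergence=conv,
        conditions=conditions,
        stability=stability,
        first_passage=fp,
        limit_matches_expected=matches,
        mismatch=mismatch,
    )


@dataclass(frozen=True)
class SweepReport:
    """Comparative dynamics of one parameter over an ordered value list."""

    parameter: str
    values: tuple[float, ...]
    reports: tuple[ScenarioReport, ...]
    grid: np.ndarray
    #: component -> interpolated trajectories, shape (len(values), len(grid))
    component_curves: dict[str, np.ndarray]
    #: component -> True when the curve is weakly increasing across the
    #: swept values at every grid time (tolerance 1e-7)
    dominance: dict[str, bool]


def sweep(
    base: Scenario,
    parameter: str,
    values: list[float],
    grid_points: int = 512,
    tol: float = 1e-7,
) -> SweepReport:
    """Re-run a scenario for each value of one parameter and compare orbits.

    Trajectories are interpolated onto a shared uniform time grid (adaptive
    solvers store different time points per run) and checked for weak
    pointwise dominance across the swept values.
    """
    if parameter not in base.params.to_dict(include_complements=True):
        raise ParameterError(f"unknown parameter {parameter!r}")
    if not values:
        raise ParameterError("values must be non-empty")
    reports = []
    for v in values:
        scen = replace(
            base,
            name=f"{base.name}[{parameter}={v}]",
            params=base.params.replace(**{parameter: v}),
            expected_limit=None,
        )
        reports.append(run_scenario(scen))
    grid = np.linspace(0.0, base.settings.t_end, grid_points)
    curves = {
        c: np.vstack([
            np.interp(grid, r.trajectory.times, r.trajectory.component(c))
            for r in reports
        ])
        for c in ("x", "y", "z")
    }
    dominance = {
        c: bool(np.all(np.diff(curves[c], axis=0) >= -tol)) for c in ("x", "y", "z")
    }
    return SweepReport(
        parameter=parameter,
        values=tuple(values),
        reports=tuple(reports),
        grid=grid,
        component_curves=curves,
        dominance=dominance,
    )
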