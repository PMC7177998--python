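"""Replicator dynamics on the unit cube.

The three population shares evolve by

    dx/dt = x (1 - x) G(x, y, z)
    dy/dt = y (1 - y) E(x, y, z)
    dz/dt = z (1 - z) H(x, y, z)

with the utility differences G, E, H from :mod:`agrigame.model`.  Every face
of the cube is invariant (the logistic factors vanish at 0 and 1), so the
cube itself is forward-invariant; trajectories can only leave it through
numerical error, which is clamped within a small tolerance and treated as a
solver failure beyond it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .errors import ContractViolationError, IntegrationError
from .model import GameParameters, MixedState, _geh

__all__ = [
    "IntegrationSettings",
    "Trajectory",
    "ConvergenceResult",
    "vector_field",
    "integrate",
    "limit_state",
    "first_passage_time",
    "VERTEX_LABELS",
]

#: Cube corners in the canonical labelling of the stability analysis.
VERTEX_LABELS: dict[str, tuple[float, float, float]] = {
    "E1": (0.0, 0.0, 0.0),
    "E2": (0.0, 0.0, 1.0),
    "E3": (0.0, 1.0, 0.0),
    "E4": (1.0, 0.0, 0.0),
    "E5": (1.0, 1.0, 0.0),
    "E6": (1.0, 0.0, 1.0),
    "E7": (0.0, 1.0, 1.0),
    "E8": (1.0, 1.0, 1.0),
}


@dataclass(frozen=True)
class IntegrationSettings:
    """Solver controls for :func:`integrate`.

    ``t_end`` defaults to the standard simulation horizon of 300 time units;
    slow-converging scenarios extend it.  ``clamp_tol`` bounds how far a
    stored state may stray outside [0, 1] before the run is declared failed.
    """

    t_end: float = 300.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    max_step: float | None = None
    clamp_tol: float = 1e-12

    def __post_init__(self) -> None:
        if self.t_end <= 0:
            raise ContractViolationError(f"t_end must be positive, got {self.t_end}")
        if self.rel_tol <= 0 or self.abs_tol <= 0:
            raise ContractViolationError("solver tolerances must be positive")

    def halved(self) -> "IntegrationSettings":
        """Same settings with both tolerances halved (grid-refinement checks)."""
        return replace(self, rel_tol=self.rel_tol / 2, abs_tol=self.abs_tol / 2)


@dataclass(frozen=True)
class Trajectory:
    """An integrated orbit: strictly increasing times and matching states."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 3), columns x, y, z
    params: GameParameters

    def __post_init__(self) -> None:
        if len(self.times) != len(self.states):
            raise ContractViolationError("times and states length mismatch")
        if len(self.times) and np.any(np.diff(self.times) <= 0):
            raise ContractViolationError("times must be strictly increasing")

    def __len__(self) -> int:
        return len(self.times)

    @property
    def final_state(self) -> MixedState:
        x, y, z = self.states[-1]
        return MixedState(float(x), float(y), float(z), t=float(self.times[-1]))

    def component(self, name: str) -> np.ndarray:
        return self.states[:, "xyz".index(name)]

    def interpolate(self, grid: np.ndarray) -> np.ndarray:
        """Linear interpolation of all three components onto a time grid."""
        return np.column_stack(
            [np.interp(grid, self.times, self.states[:, j]) for j in range(3)]
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times, "x": self.states[:, 0], "y": self.states[:, 1], "z": self.states[:, 2]}
        )


@dataclass(frozen=True)
class ConvergenceResult:
    """Limit diagnosis of a trajectory."""

    limit: MixedState | None
    converged: bool
    residual: float  # vector-field norm at the final state
    matched_vertex: str | None  # E1..E8 when the limit sits at a corner


def vector_field(
    params: GameParameters, state: MixedState | tuple[float, float, float]
) -> np.ndarray:
    """Right-hand side (dx/dt, dy/dt, dz/dt) of the replicator system."""
    if isinstance(state, MixedState):
        x, y, z = state.as_tuple()
    else:
        x, y, z = state
    G, E, H = _geh(params, x, y, z)
    return np.array([x * (1 - x) * G, y * (1 - y) * E, z * (1 - z) * H])


def integrate(
    params: GameParameters,
    initial: MixedState,
    settings: IntegrationSettings | None = None,
) -> Trajectory:
    """Integrate the replicator system from ``initial`` over [0, t_end].

    Uses an adaptive Runge-Kutta 4(5) scheme.  Coordinates that start at
    exactly 0 or 1 stay there identically (their derivative is exactly zero).
    States within ``clamp_tol`` outside the cube are snapped to the boundary;
    larger excursions raise :class:`IntegrationError`.
    """
    s = settings or IntegrationSettings()

    def rhs(_t, v):
        x, y, z = v
        G, E, H = _geh(params, x, y, z)
        return (x * (1 - x) * G, y * (1 - y) * E, z * (1 - z) * H)

    sol = solve_ivp(
        rhs,
        (0.0, s.t_end),
        np.array(initial.as_tuple(), dtype=float),
        method="RK45",
        rtol=s.rel_tol,
        atol=s.abs_tol,
        max_step=s.max_step if s.max_step is not None else np.inf,
        dense_output=False,
    )
    if not sol.success:
        raise IntegrationError(f"ODE solver failed: {sol.message}", t_reached=float(sol.t[-1]))

    states = sol.y.T.copy()
    overshoot = max(float(np.max(states - 1.0, initial=0.0)), float(np.max(-states, initial=0.0)))
    if overshoot > s.clamp_tol:
        raise IntegrationError(
            f"trajectory left the unit cube by {overshoot:.3e} (> clamp_tol {s.clamp_tol:.3e})",
            t_reached=float(sol.t[-1]),
        )
    np.clip(states, 0.0, 1.0, out=states)
    return Trajectory(times=sol.t.copy(), states=states, params=params)


def _nearest_vertex(state: np.ndarray, tol: float) -> str | None:
    for label, coords in VERTEX_LABELS.items():
        if np.max(np.abs(state - np.array(coords))) <= tol:
            return label
    return None


def limit_state(
    traj: Trajectory, vertex_tol: float = 1e-3, residual_tol: float = 1e-8
) -> ConvergenceResult:
    """Diagnose the limit of a trajectory.

    Converged means the vector-field norm at the final state is below
    ``residual_tol`` (the state is numerically at rest).  When the final
    state additionally lies within ``vertex_tol`` of a cube corner, the
    corner's label is reported.
    """
    if len(traj) == 0:
        raise ContractViolationError("empty trajectory")
    final = traj.states[-1]
    residual = float(np.linalg.norm(vector_field(traj.params, tuple(final))))
    converged = residual < residual_tol
    matched = _nearest_vertex(final, vertex_tol)
    limit = traj.final_state if converged else None
    return ConvergenceResult(
        limit=limit, converged=converged, residual=residual, matched_vertex=matched
    )


def first_passage_time(
    traj: Trajectory, component: str, threshold: float
) -> float | None:
    """Earliest time the component reaches ``threshold``, or None if never.

    Linear interpolation between stored points; a component already at the
    threshold at t=0 returns 0.
    """
    if component not in ("x", "y", "z"):
        raise ContractViolationError(f"component must be one of x, y, z; got {component!r}")
    if not 0.0 < threshold < 1.0:
        raise ContractViolationError(f"threshold must be in (0,1), got {threshold}")
    values = traj.component(component)
    idx = np.nonzero(values >= threshold)[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    if i == 0:
        return float(traj.times[0])
    t0, t1 = traj.times[i - 1], traj.times[i]
    v0, v1 = values[i - 1], values[i]
    if v1 == v0:
        return float(t1)
    return float(t0 + (threshold - v0) * (t1 - t0) / (v1 - v0))
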