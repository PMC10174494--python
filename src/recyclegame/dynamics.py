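"""Replicator dynamics of the three-population game.

The state (x, y, z) lives in the unit cube; each coordinate follows a
one-population replicator equation

    dx/dt = x (1 - x) * gov_gap(y, z)
    dy/dt = y (1 - y) * firm_gap(x)
    dz/dt = z (1 - z) * consumer_gap(x)

where the gaps are the payoff advantages from :mod:`recyclegame.game_model`.
The logistic factor p(1-p) keeps each share in [0, 1] and makes all eight
cube vertices fixed points.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .game_model import _check_state, payoff_gaps
from .params import GameParameters

__all__ = [
    "IntegrationSettings",
    "Trajectory",
    "IntegrationError",
    "VERTICES",
    "replicator_rhs",
    "integrate",
    "limit_point",
    "basin_map",
]

#: The eight pure-strategy vertices of the cube, in E1..E8 order.
VERTICES: tuple[tuple[int, int, int], ...] = (
    (0, 0, 0), (0, 0, 1), (0, 1, 0), (0, 1, 1),
    (1, 0, 0), (1, 0, 1), (1, 1, 0), (1, 1, 1),
)

#: Round-off beyond this magnitude outside [0,1] is treated as solver failure.
_CLIP_FAILURE = 1e-6


class IntegrationError(RuntimeError):
    """Integration failed; carries the last valid state reached."""

    def __init__(self, message: str, last_state: Optional[tuple[float, float, float]] = None):
        super().__init__(message)
        self.last_state = last_state


@dataclass(frozen=True)
class IntegrationSettings:
    """Solver and convergence settings for trajectory integration.

    ``t_max`` is the horizon in abstract replicator time.  The trajectory is
    sampled on a uniform grid of spacing ``dt_sample`` (post-hoc, from the
    adaptive solver's dense output).  ``convergence_tol`` and
    ``convergence_window`` define when a trajectory is considered to have
    reached a vertex: distance below the tolerance sustained over the window.
    """

    t_max: float = 100.0
    rel_tol: float = 1e-8
    abs_tol: float = 1e-10
    convergence_tol: float = 1e-3
    convergence_window: float = 10.0
    dt_sample: float = 0.1

    def __post_init__(self) -> None:
        for name in ("t_max", "rel_tol", "abs_tol", "convergence_tol",
                     "convergence_window", "dt_sample"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass(frozen=True)
class Trajectory:
    """A sampled solution of the replicator system."""

    times: np.ndarray
    states: np.ndarray  # shape (n, 3)
    params: GameParameters = field(repr=False)

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        s = np.asarray(self.states, dtype=float)
        if t.ndim != 1 or s.shape != (t.size, 3):
            raise ValueError("times must be 1-D and states (n, 3)")
        if t.size and np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "states", s)

    @property
    def terminal_state(self) -> tuple[float, float, float]:
        return tuple(self.states[-1])

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"t": self.times,
             "x": self.states[:, 0],
             "y": self.states[:, 1],
             "z": self.states[:, 2]}
        )


def replicator_rhs(params: GameParameters, state: Sequence[float]) -> tuple[float, float, float]:
    """Right-hand side of the replicator system at a state in the cube."""
    x, y, z = _check_state(state)
    gov, firm, consumer = payoff_gaps(params, (x, y, z))
    return (x * (1.0 - x) * gov,
            y * (1.0 - y) * firm,
            z * (1.0 - z) * consumer)


def integrate(
    params: GameParameters,
    initial: Sequence[float],
    settings: IntegrationSettings | None = None,
) -> Trajectory:
    """Integrate the replicator system from an initial state.

    Uses an adaptive explicit Runge-Kutta method (RK45).  Sampled states are
    clipped to [0, 1]; clipping beyond round-off magnitude raises
    :class:`IntegrationError`.  Deterministic for fixed inputs.
    """
    if settings is None:
        settings = IntegrationSettings()
    x0 = np.asarray(_check_state(initial), dtype=float)

    def rhs(_t: float, s: np.ndarray) -> np.ndarray:
        # the solver may step a hair outside the cube; evaluate on the clip
        c = np.clip(s, 0.0, 1.0)
        gov, firm, consumer = payoff_gaps(params, c)
        return np.array([c[0] * (1 - c[0]) * gov,
                         c[1] * (1 - c[1]) * firm,
                         c[2] * (1 - c[2]) * consumer])

    n = int(round(settings.t_max / settings.dt_sample)) + 1
    t_eval = np.linspace(0.0, settings.t_max, n)
    sol = solve_ivp(
        rhs, (0.0, settings.t_max), x0,
        method="RK45", t_eval=t_eval,
        rtol=settings.rel_tol, atol=settings.abs_tol,
    )
    if not sol.success:
        last = tuple(sol.y[:, -1]) if sol.y.size else tuple(x0)
        raise IntegrationError(f"solver failed: {sol.message}", last_state=last)
    states = sol.y.T
    excess = max(float(np.max(states - 1.0, initial=0.0)),
                 float(np.max(-states, initial=0.0)))
    if excess > _CLIP_FAILURE:
        raise IntegrationError(
            f"trajectory escaped the unit cube by {excess:.3e}",
            last_state=tuple(states[-1]),
        )
    return Trajectory(times=sol.t, states=np.clip(states, 0.0, 1.0), params=params)


def limit_point(
    traj: Trajectory,
    tol: float = 1e-3,
    window: float = 10.0,
) -> Optional[tuple[int, int, int]]:
    """Vertex the trajectory has settled at, or None.

    A vertex qualifies when the Chebyshev distance from the trajectory to it
    stays below ``tol`` over the final ``window`` time units (or over the
    whole trajectory if shorter).
    """
    if traj.times.size == 0:
        raise ValueError("empty trajectory")
    t_end = traj.times[-1]
    mask = traj.times >= t_end - window
    tail = traj.states[mask]
    for vertex in VERTICES:
        dist = np.max(np.abs(tail - np.asarray(vertex, dtype=float)), axis=1)
        if np.all(dist < tol):
            return vertex
    return None


def basin_map(
    params: GameParameters,
    grid_n: int,
    settings: IntegrationSettings | None = None,
) -> dict[tuple[float, float, float], Optional[tuple[int, int, int]]]:
    """Limiting vertex from each point of an interior midpoint grid.

    The grid has ``grid_n`` points per axis at the midpoints of an equal
    subdivision of [0, 1] (all strictly interior).  Integration failures at
    individual points are recorded as None rather than aborting the map.
    """
    if grid_n < 2:
        raise ValueError("grid_n must be >= 2")
    if settings is None:
        settings = IntegrationSettings()
    coords = (np.arange(grid_n) + 0.5) / grid_n
    result: dict[tuple[float, float, float], Optional[tuple[int, int, int]]] = {}
    for x in coords:
        for y in coords:
            for z in coords:
                key = (float(x), float(y), float(z))
                try:
                    traj = integrate(params, key, settings)
                except IntegrationError:
                    result[key] = None
                    continue
                result[key] = limit_point(
                    traj, settings.convergence_tol, settings.convergence_window
                )
    return result
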