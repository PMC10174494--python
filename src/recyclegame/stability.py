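"""Jacobian, vertex eigenvalues and Lyapunov classification.

At any cube vertex the Jacobian of the replicator field is diagonal, so the
eigenvalues are its diagonal entries in closed form: each is the local payoff
gap for that population, negated when the vertex plays the first-named
strategy (strong / active) there.  Classification follows the Lyapunov
indirect method on eigenvalue signs: all negative means asymptotically
stable (an ESS of the underlying game), all positive unstable, mixed signs a
saddle; an eigenvalue within tolerance of zero makes the vertex
non-hyperbolic and linearisation inconclusive.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd

from .game_model import _check_state, payoff_gaps
from .params import GameParameters

__all__ = [
    "EquilibriumPoint",
    "EigenTriple",
    "StabilityClass",
    "StabilityReport",
    "jacobian",
    "pure_equilibria",
    "vertex_eigenvalues",
    "classify_vertex",
    "stability_table",
    "find_ess",
    "interior_gap_roots",
]

DEFAULT_EPS = 1e-9


class EquilibriumPoint(NamedTuple):
    """A pure-strategy equilibrium: vertex coordinates plus its E1..E8 label."""

    coordinates: tuple[int, int, int]
    label: str


#: Fixed bijection between labels and vertex coordinates.
_EQUILIBRIA: tuple[EquilibriumPoint, ...] = (
    EquilibriumPoint((0, 0, 0), "E1"),
    EquilibriumPoint((0, 0, 1), "E2"),
    EquilibriumPoint((0, 1, 0), "E3"),
    EquilibriumPoint((0, 1, 1), "E4"),
    EquilibriumPoint((1, 0, 0), "E5"),
    EquilibriumPoint((1, 0, 1), "E6"),
    EquilibriumPoint((1, 1, 0), "E7"),
    EquilibriumPoint((1, 1, 1), "E8"),
)


class EigenTriple(NamedTuple):
    """Jacobian eigenvalues at a vertex, ordered government, firm, consumer."""

    lambda1: float
    lambda2: float
    lambda3: float


class StabilityClass(enum.Enum):
    ASYMPTOTICALLY_STABLE = "asymptotically_stable"
    UNSTABLE = "unstable"
    SADDLE = "saddle"
    NON_HYPERBOLIC = "non_hyperbolic"


def pure_equilibria() -> tuple[EquilibriumPoint, ...]:
    """The 8 pure-strategy equilibria in E1..E8 order (parameter-independent)."""
    return _EQUILIBRIA


def equilibrium(label_or_coords: str | Sequence[int]) -> EquilibriumPoint:
    """Look up an equilibrium by label ("E5") or coordinates ((1, 0, 0))."""
    for eq in _EQUILIBRIA:
        if label_or_coords == eq.label or tuple(label_or_coords) == eq.coordinates:
            return eq
    raise KeyError(f"unknown equilibrium {label_or_coords!r}")


def jacobian(params: GameParameters, state: Sequence[float]) -> np.ndarray:
    """Analytic 3x3 Jacobian of the replicator field at a state in the cube."""
    x, y, z = _check_state(state)
    p = params
    gov, firm, consumer = payoff_gaps(p, (x, y, z))
    return np.array([
        [(1 - 2 * x) * gov, -x * (1 - x) * (p.A1 + p.F1), -x * (1 - x) * p.A2],
        [y * (1 - y) * (p.A1 + p.F1), (1 - 2 * y) * firm, 0.0],
        [z * (1 - z) * p.A2, 0.0, (1 - 2 * z) * consumer],
    ])


def vertex_eigenvalues(params: GameParameters, eq: EquilibriumPoint) -> EigenTriple:
    """Closed-form Jacobian eigenvalues at a pure-strategy equilibrium.

    At vertex (x*, y*, z*) the off-diagonal entries vanish, leaving
    lambda1 = (1 - 2x*) gov_gap(y*, z*), and similarly for the firm and
    consumer directions.
    """
    x, y, z = eq.coordinates
    gov, firm, consumer = payoff_gaps(params, (float(x), float(y), float(z)))
    return EigenTriple(
        lambda1=(1 - 2 * x) * gov,
        lambda2=(1 - 2 * y) * firm,
        lambda3=(1 - 2 * z) * consumer,
    )


def classify_vertex(
    params: GameParameters,
    eq: EquilibriumPoint,
    eps: float = DEFAULT_EPS,
) -> StabilityClass:
    """Lyapunov classification of a vertex by eigenvalue signs."""
    if eps <= 0:
        raise ValueError("eps must be positive")
    lams = vertex_eigenvalues(params, eq)
    if any(abs(lam) <= eps for lam in lams):
        return StabilityClass.NON_HYPERBOLIC
    if all(lam < 0 for lam in lams):
        return StabilityClass.ASYMPTOTICALLY_STABLE
    if all(lam > 0 for lam in lams):
        return StabilityClass.UNSTABLE
    return StabilityClass.SADDLE


@dataclass(frozen=True)
class StabilityReport:
    """Eigenvalues and classification for all 8 pure-strategy equilibria."""

    rows: tuple[tuple[EquilibriumPoint, EigenTriple, StabilityClass], ...]

    def __post_init__(self) -> None:
        if len(self.rows) != 8:
            raise ValueError("a stability report has exactly 8 rows")

    def stable_vertices(self) -> frozenset[tuple[int, int, int]]:
        return frozenset(
            eq.coordinates for eq, _, cls in self.rows
            if cls is StabilityClass.ASYMPTOTICALLY_STABLE
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "equilibrium": [eq.label for eq, _, _ in self.rows],
                "x": [eq.coordinates[0] for eq, _, _ in self.rows],
                "y": [eq.coordinates[1] for eq, _, _ in self.rows],
                "z": [eq.coordinates[2] for eq, _, _ in self.rows],
                "lambda1": [lams.lambda1 for _, lams, _ in self.rows],
                "lambda2": [lams.lambda2 for _, lams, _ in self.rows],
                "lambda3": [lams.lambda3 for _, lams, _ in self.rows],
                "stability": [cls.value for _, _, cls in self.rows],
            }
        )


def stability_table(params: GameParameters, eps: float = DEFAULT_EPS) -> StabilityReport:
    """Eigenvalues and Lyapunov classification at every vertex."""
    return StabilityReport(
        tuple(
            (eq, vertex_eigenvalues(params, eq), classify_vertex(params, eq, eps))
            for eq in _EQUILIBRIA
        )
    )


def find_ess(params: GameParameters, eps: float = DEFAULT_EPS) -> frozenset[EquilibriumPoint]:
    """Asymptotically stable vertices (evolutionarily stable strategies)."""
    return frozenset(
        eq for eq in _EQUILIBRIA
        if classify_vertex(params, eq, eps) is StabilityClass.ASYMPTOTICALLY_STABLE
    )


def interior_gap_roots(params: GameParameters) -> dict[str, Optional[float]]:
    """Diagnostic roots of the gap functions inside (0, 1).

    Mixed-strategy rest points require the firm and consumer gaps to vanish
    at the same x, which is non-generic; they are never evolutionarily stable
    in this asymmetric game, so this is reported for diagnostics only.
    Returns the x that zeroes the firm gap and the x that zeroes the consumer
    gap (None when undefined or outside (0, 1)).
    """
    p = params

    def in_unit(v: float) -> Optional[float]:
        return v if 0.0 < v < 1.0 else None

    x_firm = None
    if p.A1 + p.F1 > 0:
        x_firm = in_unit((p.R3 - p.C3 - p.R1 + p.C1) / (p.A1 + p.F1))
    x_consumer = None
    if p.A2 > 0:
        x_consumer = in_unit((p.R4 - p.C4 - p.R2 + p.C2) / p.A2)
    return {"x_firm_gap_root": x_firm, "x_consumer_gap_root": x_consumer}
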