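"""Printed parameterizations and a regime-constrained parameter generator.

The model has no empirical data: the study's inputs are a baseline parameter
set chosen to satisfy the ordering and opportunism constraints, three
simulation scenarios that override the gains to select a regime, and random
parameter sets drawn inside each inequality regime.  This module supplies
all of them, so every theorem and stability table is testable.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .game_model import Regime, RegimeLabel, classify_regime, gap_thresholds
from .params import PARAM_NAMES, GameParameters
from .stability import find_ess

__all__ = [
    "ScenarioSpec",
    "SamplerConfig",
    "SamplingError",
    "SCENARIO_NAMES",
    "baseline_parameters",
    "scenario",
    "sample_parameters",
    "sweep_relative_gain",
]

#: Baseline values shared by all scenarios (gains R5, R6 are scenario-specific).
_BASELINE: Mapping[str, float] = {
    "A1": 5, "A2": 4, "F1": 3,
    "C1": 5, "C2": 4, "C3": 4, "C4": 3, "C5": 5, "C6": 4,
    "M1": 3, "M2": 1, "M3": 2, "M4": 1,
    "B1": 3, "B2": 2,
    "R1": 10, "R2": 6, "R3": 12, "R4": 8,
}

#: Scenario overrides and the stability point each converges to.
_SCENARIOS: Mapping[str, tuple[Mapping[str, float], Optional[tuple[int, int, int]]]] = {
    "baseline": ({"R5": 30, "R6": 14}, None),
    "s6_1": ({"R5": 30, "R6": 14}, (1, 1, 1)),
    "s6_2": ({"R1": 15, "R2": 10, "R5": 30, "R6": 20}, (0, 1, 1)),
    "s6_3": ({"R3": 18, "R4": 10, "R5": 30, "R6": 14}, (1, 0, 0)),
}

SCENARIO_NAMES: tuple[str, ...] = tuple(_SCENARIOS)


@dataclass(frozen=True)
class ScenarioSpec:
    """A named parameterization plus the vertex it is expected to converge to."""

    name: str
    params: GameParameters
    expected_vertex: Optional[tuple[int, int, int]]


def baseline_parameters(R5: float = 30.0, R6: float = 14.0) -> GameParameters:
    """The common baseline parameter set.

    The baseline fixes every parameter except the government's gains; R5 and
    R6 default to the high-relative-gain values and are overridden by the
    scenarios and sweeps that vary the relative gain.
    """
    return GameParameters(**dict(_BASELINE), R5=R5, R6=R6)


def scenario(name: str) -> ScenarioSpec:
    """Look up a named scenario ("s6_1", "s6_2", "s6_3" or "baseline")."""
    try:
        overrides, vertex = _SCENARIOS[name]
    except KeyError:
        raise KeyError(
            f"unknown scenario {name!r}; choose from {', '.join(SCENARIO_NAMES)}"
        ) from None
    params = GameParameters(**{**_BASELINE, **overrides})
    return ScenarioSpec(name=name, params=params, expected_vertex=vertex)


# ----------------------------------------------------------------------
# Regime-constrained sampling
# ----------------------------------------------------------------------

class SamplingError(RuntimeError):
    """Rejection sampling exhausted its budget for the requested regime."""


@dataclass(frozen=True)
class SamplerConfig:
    """Configuration for regime-constrained rejection sampling.

    Each parameter is drawn uniformly on its range (default [0, 20], the
    magnitude of the printed parameterizations).  The government's gain R5 is
    drawn conditionally: the relative gain R5 - R6 is drawn uniformly on the
    regime's admissible interval (truncated to width 20 when unbounded),
    which keeps rejection rates practical without touching any other
    parameter's distribution.  Draws within ``boundary_margin`` of a
    regime-defining equality are rejected so classifications stay hyperbolic.
    """

    regime: Regime
    seed: int
    ranges: Mapping[str, tuple[float, float]] = field(default_factory=dict)
    max_rejections: int = 100_000
    boundary_margin: float = 1e-6

    def __post_init__(self) -> None:
        if self.max_rejections < 1:
            raise ValueError("max_rejections must be >= 1")
        for name, (lo, hi) in self.ranges.items():
            if name not in PARAM_NAMES:
                raise ValueError(f"unknown parameter in ranges: {name}")
            if not lo < hi:
                raise ValueError(f"empty range for {name}: ({lo}, {hi})")


_DEFAULT_RANGE = (0.0, 20.0)

#: Relative-gain interval (as offsets from the thresholds) per target regime.
#: None means the regime places no constraint through that bound.
_GAIN_INTERVAL: Mapping[Regime, tuple[Optional[str], Optional[str]]] = {
    Regime.T1_ALL_COOPERATE: ("upper", None),
    Regime.T2_ALL_DEFECT: (None, "lower"),
    Regime.T3_WEAK_GOV_COOP: (None, "upper"),
    Regime.T3_STRONG_GOV_COOP: ("upper", None),
    Regime.T4_WEAK_GOV_DEFECT: (None, "lower"),
    Regime.T4_STRONG_GOV_DEFECT: ("lower", None),
    Regime.NO_ESS_WINDOW: ("lower", "upper"),
}


def sample_parameters(config: SamplerConfig) -> GameParameters:
    """Draw one parameter set classified into the requested regime.

    Seeded and reproducible: the same config yields the same parameters.
    Raises :class:`SamplingError` when ``max_rejections`` draws fail.
    """
    if config.regime not in _GAIN_INTERVAL:
        raise ValueError(f"cannot sample for regime {config.regime}")
    rng = np.random.default_rng(config.seed)
    margin = config.boundary_margin

    def rand(name: str) -> float:
        lo, hi = config.ranges.get(name, _DEFAULT_RANGE)
        return float(rng.uniform(lo, hi))

    for _ in range(config.max_rejections):
        draw = {name: rand(name) for name in PARAM_NAMES if name != "R5"}
        # ordering constraints (rejection keeps per-parameter uniformity)
        if not (draw["C1"] >= draw["C3"] and draw["C2"] >= draw["C4"]
                and draw["C5"] >= draw["C6"]):
            continue
        probe = GameParameters(**draw, R5=draw["R6"])
        firm_opp = (draw["R3"] - draw["C3"]) - (draw["R1"] - draw["C1"])
        cons_opp = (draw["R4"] - draw["C4"]) - (draw["R2"] - draw["C2"])
        firm_eff = (draw["R1"] - draw["C1"] + draw["A1"]) - (draw["R3"] - draw["C3"] - draw["F1"])
        cons_eff = (draw["R2"] - draw["C2"] + draw["A2"]) - (draw["R4"] - draw["C4"])
        regime = config.regime
        if regime in (Regime.T3_WEAK_GOV_COOP, Regime.T3_STRONG_GOV_COOP):
            if not (firm_opp < -margin and cons_opp < -margin):
                continue
        elif regime in (Regime.T4_WEAK_GOV_DEFECT, Regime.T4_STRONG_GOV_DEFECT):
            if not (firm_eff < -margin and cons_eff < -margin):
                continue
        else:  # baseline regimes: T1, T2, NO_ESS_WINDOW
            if not (firm_opp > margin and cons_opp > margin
                    and firm_eff > margin and cons_eff > margin):
                continue
        lower, upper = gap_thresholds(probe)
        lo_kind, hi_kind = _GAIN_INTERVAL[regime]
        thresholds = {"lower": lower, "upper": upper}
        gain_lo = thresholds[lo_kind] if lo_kind else None
        gain_hi = thresholds[hi_kind] if hi_kind else None
        if gain_lo is None:
            gain_lo = gain_hi - 20.0
        elif gain_hi is None:
            gain_hi = gain_lo + 20.0
        gain_lo += margin
        gain_hi -= margin
        if gain_hi <= gain_lo:
            continue
        d = float(rng.uniform(gain_lo, gain_hi))
        params = probe.replace(R5=draw["R6"] + d)
        if classify_regime(params, eps=margin).label is regime:
            return params
    raise SamplingError(
        f"no parameter set found for regime {config.regime.value} "
        f"after {config.max_rejections} draws (seed {config.seed})"
    )


def sweep_relative_gain(
    base: GameParameters,
    R5_values: Sequence[float],
    eps: float = 1e-9,
) -> pd.DataFrame:
    """Regime and ESS set as the government's gain R5 sweeps across thresholds.

    Returns one row per R5 value with columns R5, relative_gain, regime and
    stable_vertices (sorted E-labels, '-' when none).
    """
    if len(R5_values) == 0:
        raise ValueError("R5_values must be non-empty")
    rows = []
    for r5 in R5_values:
        params = base.replace(R5=float(r5))
        label: RegimeLabel = classify_regime(params, eps=eps)
        ess = find_ess(params, eps=eps)
        rows.append(
            {
                "R5": float(r5),
                "relative_gain": params.R5 - params.R6,
                "regime": label.label.value,
                "stable_vertices": ";".join(sorted(eq.label for eq in ess)) or "-",
            }
        )
    return pd.DataFrame(rows)
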