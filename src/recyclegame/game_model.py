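"""Payoff matrix, expected payoffs and parameter-regime classification.

Stage game: the government plays {strong, weak} regulation, firms play
{active, passive} participation in recycling, consumers play {active,
passive}.  Each of the 8 pure strategy profiles yields a payoff triple
(government, firm, consumer) built from the parameter symbols.

Population shares: ``x`` is the probability of strong regulation, ``y`` of
firm active participation, ``z`` of consumer active participation.  Expected
payoffs are bilinear aggregations of the matrix over the other two
populations' mixtures; the per-population payoff *gaps* (advantage of the
first strategy over the second) drive the replicator dynamics.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Mapping, NamedTuple, Sequence

import numpy as np

from .params import GameParameters

__all__ = [
    "StrategyProfile",
    "PayoffTriple",
    "PayoffMatrix",
    "ExpectedPayoffs",
    "RegimeFlags",
    "Regime",
    "RegimeLabel",
    "PROFILES",
    "build_payoff_matrix",
    "expected_payoffs",
    "payoff_gaps",
    "gap_thresholds",
    "check_regime_flags",
    "classify_regime",
]


class StrategyProfile(NamedTuple):
    """One pure strategy profile of the three populations."""

    gov: str        # "strong" | "weak"
    firm: str       # "active" | "passive"
    consumer: str   # "active" | "passive"


class PayoffTriple(NamedTuple):
    gov: float
    firm: float
    consumer: float


#: The 8 pure strategy profiles, gov-major then firm then consumer, with the
#: first-named strategy (strong/active) first.
PROFILES: tuple[StrategyProfile, ...] = tuple(
    StrategyProfile(g, f, c)
    for g in ("strong", "weak")
    for f in ("active", "passive")
    for c in ("active", "passive")
)


@dataclass(frozen=True)
class PayoffMatrix:
    """Mapping from each of the 8 pure strategy profiles to a payoff triple."""

    entries: tuple[tuple[StrategyProfile, PayoffTriple], ...]

    def __post_init__(self) -> None:
        if tuple(p for p, _ in self.entries) != PROFILES:
            raise ValueError("payoff matrix must have the 8 canonical profiles in order")

    def __getitem__(self, profile: StrategyProfile) -> PayoffTriple:
        for p, triple in self.entries:
            if p == profile:
                return triple
        raise KeyError(profile)

    def items(self) -> Iterable[tuple[StrategyProfile, PayoffTriple]]:
        return iter(self.entries)

    def as_dict(self) -> dict[StrategyProfile, PayoffTriple]:
        return dict(self.entries)


def _cell(p: GameParameters, gov: str, firm: str, consumer: str) -> PayoffTriple:
    strong = gov == "strong"
    f_active = firm == "active"
    c_active = consumer == "active"

    # Government: gross gain minus regulation cost, minus incentives and
    # subsidies paid under strong regulation, plus fines collected from
    # passive firms, minus externality losses from passive firms/consumers.
    g = (p.R5 - p.C5) if strong else (p.R6 - p.C6)
    if strong:
        g -= p.B1 + p.B2          # lump-sum subsidies always paid when strong
        if f_active:
            g -= p.A1
        else:
            g += p.F1
        if c_active:
            g -= p.A2
    if not f_active:
        g -= p.M1
    if not c_active:
        g -= p.M3

    # Firm: net gain of its own strategy, plus incentives/subsidy and minus
    # the fine under strong regulation, minus the loss from consumer passivity.
    f = (p.R1 - p.C1) if f_active else (p.R3 - p.C3)
    if strong:
        f += p.B1
        if f_active:
            f += p.A1
        else:
            f -= p.F1
    if not c_active:
        f -= p.M4

    # Consumer: net gain of its own strategy, plus incentive/subsidy under
    # strong regulation, minus the loss from firm passivity.
    c = (p.R2 - p.C2) if c_active else (p.R4 - p.C4)
    if strong:
        c += p.B2
        if c_active:
            c += p.A2
    if not f_active:
        c -= p.M2

    return PayoffTriple(g, f, c)


def build_payoff_matrix(params: GameParameters) -> PayoffMatrix:
    """Construct the 8-cell payoff matrix from a validated parameter set.

    The cell formulas are the per-profile terms of the expected-payoff
    equations (which are algebraically consistent with the replicator system
    the whole analysis rests on); regenerating from the same parameters is
    bit-identical.
    """
    return PayoffMatrix(tuple((prof, _cell(params, *prof)) for prof in PROFILES))


# ----------------------------------------------------------------------
# Expected payoffs and gaps
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class ExpectedPayoffs:
    """Pure-strategy expected payoffs and population means at a mixed state."""

    gov_strong: float
    gov_weak: float
    gov_mean: float
    firm_active: float
    firm_passive: float
    firm_mean: float
    consumer_active: float
    consumer_passive: float
    consumer_mean: float


def _check_state(state: Sequence[float]) -> tuple[float, float, float]:
    arr = np.asarray(state, dtype=float)
    if arr.shape != (3,):
        raise ValueError(f"state must have 3 components, got shape {arr.shape}")
    if np.any(arr < 0.0) or np.any(arr > 1.0):
        raise ValueError(f"state {tuple(arr)} outside the unit cube [0,1]^3")
    return float(arr[0]), float(arr[1]), float(arr[2])


def expected_payoffs(params: GameParameters, state: Sequence[float]) -> ExpectedPayoffs:
    """Bilinear aggregation of the payoff matrix at population state (x, y, z)."""
    x, y, z = _check_state(state)
    m = build_payoff_matrix(params).as_dict()

    def w(prob: float, name: str, first: str) -> float:
        return prob if name == first else 1.0 - prob

    def agg(role: int, own: str, own_value: str) -> float:
        total = 0.0
        for prof, triple in m.items():
            if getattr(prof, own) != own_value:
                continue
            weight = 1.0
            if own != "gov":
                weight *= w(x, prof.gov, "strong")
            if own != "firm":
                weight *= w(y, prof.firm, "active")
            if own != "consumer":
                weight *= w(z, prof.consumer, "active")
            total += weight * triple[role]
        return total

    gov_s = agg(0, "gov", "strong")
    gov_w = agg(0, "gov", "weak")
    firm_a = agg(1, "firm", "active")
    firm_p = agg(1, "firm", "passive")
    cons_a = agg(2, "consumer", "active")
    cons_p = agg(2, "consumer", "passive")
    return ExpectedPayoffs(
        gov_strong=gov_s,
        gov_weak=gov_w,
        gov_mean=x * gov_s + (1.0 - x) * gov_w,
        firm_active=firm_a,
        firm_passive=firm_p,
        firm_mean=y * firm_a + (1.0 - y) * firm_p,
        consumer_active=cons_a,
        consumer_passive=cons_p,
        consumer_mean=z * cons_a + (1.0 - z) * cons_p,
    )


def payoff_gaps(params: GameParameters, state: Sequence[float]) -> tuple[float, float, float]:
    """Closed-form payoff advantages (strong-weak, active-passive, active-passive).

    These are the bracketed factors of the replicator field:

    * government: ``-y (A1 + F1) - z A2 + R5 - C5 - B1 - B2 + F1 - R6 + C6``
    * firm:       ``x (A1 + F1) + R1 - C1 - R3 + C3``
    * consumer:   ``x A2 + R2 - C2 - R4 + C4``
    """
    x, y, z = _check_state(state)
    p = params
    gov = (-y * (p.A1 + p.F1) - z * p.A2
           + p.R5 - p.C5 - p.B1 - p.B2 + p.F1 - p.R6 + p.C6)
    firm = x * (p.A1 + p.F1) + p.R1 - p.C1 - p.R3 + p.C3
    consumer = x * p.A2 + p.R2 - p.C2 - p.R4 + p.C4
    return gov, firm, consumer


# ----------------------------------------------------------------------
# Regime flags and classification
# ----------------------------------------------------------------------

@dataclass(frozen=True)
class RegimeFlags:
    """Boolean inequality regimes of a parameter set plus relative-gain position.

    ``relative_gain_position`` locates the government's relative gain
    ``R5 - R6`` against the lower threshold ``C5 - C6 + B1 + B2 - F1`` and
    the upper threshold ``C5 - C6 + B1 + B2 + A1 + A2``.
    """

    opportunism_under_weak: bool
    regulation_effective: bool
    high_opportunity_cost: bool
    regulation_insufficient: bool
    relative_gain_position: str  # "below_lower" | "in_window" | "above_upper"
    relative_gain: float
    lower_threshold: float
    upper_threshold: float


def gap_thresholds(params: GameParameters) -> tuple[float, float]:
    """Lower and upper thresholds for the government's relative gain R5 - R6."""
    base = params.C5 - params.C6 + params.B1 + params.B2
    return base - params.F1, base + params.A1 + params.A2


def check_regime_flags(params: GameParameters) -> RegimeFlags:
    """Evaluate the inequality regimes on (non-strict) comparisons.

    Scale-consistent: multiplying every parameter by a positive constant
    leaves every flag unchanged.
    """
    p = params
    firm_net_active = p.R1 - p.C1
    firm_net_passive = p.R3 - p.C3
    cons_net_active = p.R2 - p.C2
    cons_net_passive = p.R4 - p.C4
    lower, upper = gap_thresholds(p)
    d = p.R5 - p.R6
    if d > upper:
        position = "above_upper"
    elif d < lower:
        position = "below_lower"
    else:
        position = "in_window"
    return RegimeFlags(
        opportunism_under_weak=(firm_net_active <= firm_net_passive
                                and cons_net_active <= cons_net_passive),
        regulation_effective=(firm_net_passive - p.F1 <= firm_net_active + p.A1
                              and cons_net_passive <= cons_net_active + p.A2),
        high_opportunity_cost=(firm_net_active >= firm_net_passive
                               and cons_net_active >= cons_net_passive),
        regulation_insufficient=(firm_net_passive - p.F1 > firm_net_active + p.A1
                                 and cons_net_passive > cons_net_active + p.A2),
        relative_gain_position=position,
        relative_gain=d,
        lower_threshold=lower,
        upper_threshold=upper,
    )


class Regime(enum.Enum):
    """Theorem-predicted long-run regimes of the game."""

    T1_ALL_COOPERATE = "T1_all_cooperate"        # unique ESS E8 (1,1,1)
    T2_ALL_DEFECT = "T2_all_defect"              # unique ESS E1 (0,0,0)
    T3_WEAK_GOV_COOP = "T3_weak_gov_coop"        # unique ESS E4 (0,1,1)
    T3_STRONG_GOV_COOP = "T3_strong_gov_coop"    # unique ESS E8 (1,1,1)
    T4_WEAK_GOV_DEFECT = "T4_weak_gov_defect"    # unique ESS E1 (0,0,0)
    T4_STRONG_GOV_DEFECT = "T4_strong_gov_defect"  # unique ESS E5 (1,0,0)
    NO_ESS_WINDOW = "NO_ESS_WINDOW"              # no asymptotically stable vertex
    UNCLASSIFIED = "UNCLASSIFIED"


#: ESS vertex predicted by each regime.
_REGIME_VERTICES: Mapping[Regime, frozenset[tuple[int, int, int]]] = {
    Regime.T1_ALL_COOPERATE: frozenset({(1, 1, 1)}),
    Regime.T2_ALL_DEFECT: frozenset({(0, 0, 0)}),
    Regime.T3_WEAK_GOV_COOP: frozenset({(0, 1, 1)}),
    Regime.T3_STRONG_GOV_COOP: frozenset({(1, 1, 1)}),
    Regime.T4_WEAK_GOV_DEFECT: frozenset({(0, 0, 0)}),
    Regime.T4_STRONG_GOV_DEFECT: frozenset({(1, 0, 0)}),
    Regime.NO_ESS_WINDOW: frozenset(),
    Regime.UNCLASSIFIED: frozenset(),
}


@dataclass(frozen=True)
class RegimeLabel:
    """Classification outcome: regime plus the vertices it predicts stable."""

    label: Regime
    predicted_stable_vertices: frozenset[tuple[int, int, int]]


def _sign(v: float, eps: float) -> int:
    if v > eps:
        return 1
    if v < -eps:
        return -1
    return 0


def classify_regime(params: GameParameters, eps: float = 1e-9) -> RegimeLabel:
    """Assign a parameter set to its theorem-predicted regime.

    Theorem conditions are taken as strict inequalities; any regime-defining
    comparison within ``eps`` of equality yields UNCLASSIFIED rather than a
    guessed label.

    Branch logic (mutually exclusive away from boundaries):

    * opportunity cost of passivity strictly high for both firm and consumer
      -> cooperation regime; the ESS is (1,1,1) above the upper relative-gain
      threshold, (0,1,1) below it;
    * strong regulation strictly insufficient for both firm and consumer
      -> defection regime; the ESS is (1,0,0) above the lower threshold,
      (0,0,0) below it;
    * baseline (opportunism under weak regulation, regulation effective, all
      strict) -> (1,1,1) above the upper threshold, (0,0,0) below the lower,
      and *no* stable vertex strictly inside the window.
    """
    p = params
    opp_firm = _sign((p.R3 - p.C3) - (p.R1 - p.C1), eps)
    opp_cons = _sign((p.R4 - p.C4) - (p.R2 - p.C2), eps)
    eff_firm = _sign((p.R1 - p.C1 + p.A1) - (p.R3 - p.C3 - p.F1), eps)
    eff_cons = _sign((p.R2 - p.C2 + p.A2) - (p.R4 - p.C4), eps)
    lower, upper = gap_thresholds(p)
    d = p.R5 - p.R6
    pos_lower = _sign(d - lower, eps)
    pos_upper = _sign(d - upper, eps)

    label = Regime.UNCLASSIFIED
    if opp_firm < 0 and opp_cons < 0:
        # high opportunity cost of passivity (Theorem 3 branch)
        if pos_upper > 0:
            label = Regime.T3_STRONG_GOV_COOP
        elif pos_upper < 0:
            label = Regime.T3_WEAK_GOV_COOP
    elif eff_firm < 0 and eff_cons < 0:
        # strong regulation insufficient (Theorem 4 branch)
        if pos_lower > 0:
            label = Regime.T4_STRONG_GOV_DEFECT
        elif pos_lower < 0:
            label = Regime.T4_WEAK_GOV_DEFECT
    elif opp_firm > 0 and opp_cons > 0 and eff_firm > 0 and eff_cons > 0:
        # baseline assumptions (Theorems 1-2 and the no-ESS window)
        if pos_upper > 0:
            label = Regime.T1_ALL_COOPERATE
        elif pos_lower < 0:
            label = Regime.T2_ALL_DEFECT
        elif pos_lower > 0 and pos_upper < 0:
            label = Regime.NO_ESS_WINDOW
    return RegimeLabel(label, _REGIME_VERTICES[label])
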