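"""Model parameters for the tripartite drug-recycling game.

The model has three bounded-rational populations — a government choosing
between strong and weak regulation, drug-recycling firms choosing between
active and passive participation, and consumers choosing between active and
passive participation.  Twenty-one scalar payoff parameters describe incentives,
fines, costs, gross gains, externality losses and lump-sum subsidies.  All
values are in abstract currency units.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Mapping

__all__ = ["GameParameters", "ParameterError", "PARAM_NAMES"]

#: Canonical ordering of the 20 parameter symbols.
PARAM_NAMES: tuple[str, ...] = (
    "A1", "A2", "F1",
    "C1", "C2", "C3", "C4", "C5", "C6",
    "R1", "R2", "R3", "R4", "R5", "R6",
    "M1", "M2", "M3", "M4",
    "B1", "B2",
)
assert len(PARAM_NAMES) == 21


class ParameterError(ValueError):
    """A parameter set violates one of the model's sign or ordering constraints."""


# Parameters that must be non-negative: incentives, fines, costs, losses and
# lump-sum subsidies.  Gross gains R1..R6 are unrestricted in sign.
_NONNEGATIVE = (
    "A1", "A2", "F1",
    "C1", "C2", "C3", "C4", "C5", "C6",
    "M1", "M2", "M3", "M4",
    "B1", "B2",
)


@dataclass(frozen=True)
class GameParameters:
    """The scalar payoff parameters of the recycling game.

    Attributes
    ----------
    A1, A2
        Incentive paid to firms / consumers for active participation under
        strong regulation.
    F1
        Fine levied on passively participating firms under strong regulation.
    C1, C2
        Cost of active participation for firms / consumers.
    C3, C4
        Cost of passive participation for firms / consumers.
    C5, C6
        Cost of strong / weak government regulation.
    R1, R3
        Gross gain of firm active / passive participation.
    R2, R4
        Gross gain of consumer active / passive participation.
    R5, R6
        Gross gain of strong / weak government regulation.  ``R5 - R6`` is
        the government's *relative gain*, the quantity whose position against
        two thresholds selects the long-run regime.
    M1, M3
        Loss to the government from firm / consumer passivity.
    M2, M4
        Loss to consumers from firm passivity / to firms from consumer
        passivity.
    B1, B2
        Lump-sum subsidy to firms / consumers whenever regulation is strong.

    Constraints checked at construction: active participation costs at least
    as much as passive (``C1 >= C3``, ``C2 >= C4``), strong regulation costs
    at least as much as weak (``C5 >= C6``), and every incentive, fine, cost,
    loss and subsidy is non-negative.
    """

    A1: float
    A2: float
    F1: float
    C1: float
    C2: float
    C3: float
    C4: float
    C5: float
    C6: float
    R1: float
    R2: float
    R3: float
    R4: float
    R5: float
    R6: float
    M1: float
    M2: float
    M3: float
    M4: float
    B1: float
    B2: float

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            value = getattr(self, name)
            try:
                object.__setattr__(self, name, float(value))
            except (TypeError, ValueError) as exc:
                raise ParameterError(f"{name} is not a real scalar: {value!r}") from exc
        for name in _NONNEGATIVE:
            if getattr(self, name) < 0:
                raise ParameterError(f"{name} must be >= 0, got {getattr(self, name)}")
        for hi, lo in (("C1", "C3"), ("C2", "C4"), ("C5", "C6")):
            if getattr(self, hi) < getattr(self, lo):
                raise ParameterError(
                    f"{hi} >= {lo} violated: {hi}={getattr(self, hi)}, "
                    f"{lo}={getattr(self, lo)}"
                )

    # ------------------------------------------------------------------
    # (de)serialisation: flat JSON objects keyed by the symbol names
    # ------------------------------------------------------------------
    def to_dict(self) -> dict[str, float]:
        """Return the parameters as a flat ``{symbol: value}`` mapping."""
        return {name: getattr(self, name) for name in PARAM_NAMES}

    @classmethod
    def from_dict(cls, data: Mapping[str, float]) -> "GameParameters":
        """Build a parameter set from a flat mapping; unknown keys are rejected."""
        unknown = sorted(set(data) - set(PARAM_NAMES))
        if unknown:
            raise ParameterError(f"unknown parameter key(s): {', '.join(unknown)}")
        missing = sorted(set(PARAM_NAMES) - set(data))
        if missing:
            raise ParameterError(f"missing parameter key(s): {', '.join(missing)}")
        return cls(**{name: data[name] for name in PARAM_NAMES})

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1) + "\n")

    @classmethod
    def from_json(cls, path: str | Path) -> "GameParameters":
        return cls.from_dict(json.loads(Path(path).read_text()))

    def replace(self, **overrides: float) -> "GameParameters":
        """Return a copy with the given symbols overridden."""
        return dataclasses.replace(self, **overrides)

    def __iter__(self) -> Iterator[tuple[str, float]]:
        return iter(self.to_dict().items())
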