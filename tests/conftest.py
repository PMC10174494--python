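import numpy as np
import pytest

from recyclegame import GameParameters, baseline_parameters, scenario


@pytest.fixture(scope="session")
def baseline() -> GameParameters:
    return baseline_parameters()


@pytest.fixture(scope="session")
def scenario_specs():
    return {name: scenario(name) for name in ("s6_1", "s6_2", "s6_3")}


@pytest.fixture(scope="session")
def zero_params() -> GameParameters:
    return GameParameters(**{name: 0.0 for name in GameParameters.__dataclass_fields__})


def random_parameters(rng: np.random.Generator) -> GameParameters:
    """A valid random parameter set: non-negative draws with cost orderings."""
    draw = {name: float(rng.uniform(0, 20)) for name in
            ("A1", "A2", "F1", "M1", "M2", "M3", "M4", "B1", "B2")}
    for hi, lo in (("C1", "C3"), ("C2", "C4"), ("C5", "C6")):
        a, b = sorted(rng.uniform(0, 20, size=2))
        draw[lo], draw[hi] = float(a), float(b)
    for name in ("R1", "R2", "R3", "R4", "R5", "R6"):
        draw[name] = float(rng.uniform(-20, 40))
    return GameParameters(**draw)


def random_state(rng: np.random.Generator) -> tuple[float, float, float]:
    return tuple(rng.uniform(0, 1, size=3))
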