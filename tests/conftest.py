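import numpy as np
import pytest

from pegblock.schemes import (
    CLOSED,
    OPEN,
    Conditions,
    Edge,
    KineticScheme,
    RateLaw,
    build_blockade_scheme,
)
from pegblock.simulate import default_rate_table


@pytest.fixture
def two_state():
    """C <-> O with opening 50 s^-1, closing 100 s^-1."""
    return KineticScheme(
        ["C", "O"],
        {"C": CLOSED, "O": OPEN},
        [
            Edge("C", "O", RateLaw(50.0), "opening"),
            Edge("O", "C", RateLaw(100.0), "closing"),
        ],
    )


@pytest.fixture
def three_state():
    """C1 <-> O <-> C2: two closed states communicating only through O."""
    return KineticScheme(
        ["C1", "O", "C2"],
        {"C1": CLOSED, "O": OPEN, "C2": CLOSED},
        [
            Edge("C1", "O", RateLaw(200.0), "beta1"),
            Edge("O", "C1", RateLaw(80.0), "alpha1"),
            Edge("O", "C2", RateLaw(30.0), "alpha2"),
            Edge("C2", "O", RateLaw(10.0), "beta2"),
        ],
    )


@pytest.fixture
def blockade_scheme():
    """The default AChR gating + one-mode blockade scheme."""
    return build_blockade_scheme(default_rate_table(1))


@pytest.fixture
def standard_conditions():
    return Conditions(conc_ACh=100.0, conc_blocker=10.0, V_m=0.0)
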