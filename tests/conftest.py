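import numpy as np
import pytest

from macroir import (
    Epoch,
    ObservationParams,
    Protocol,
    TrimerParams,
    scheme_from_config,
)

THREE_STATE_CFG = """
[scheme]
states = ["C", "F", "O"]
classes = [0, 0, 3]

[scheme.params]
k1 = 0.05
k_1 = 200.0
k2 = 300.0
k_2 = 150.0

[[scheme.edge]]
from = "C"
to = "F"
rate = "k1"
conc = true

[[scheme.edge]]
from = "F"
to = "C"
rate = "k_1"

[[scheme.edge]]
from = "F"
to = "O"
rate = "k2"

[[scheme.edge]]
from = "O"
to = "F"
rate = "k_2"
"""

TWO_STATE_CFG = """
[scheme]
states = ["C", "O"]
classes = [0, 3]

[scheme.params]
k_on = 0.05
k_off = 200.0

[[scheme.edge]]
from = "C"
to = "O"
rate = "k_on"
conc = true

[[scheme.edge]]
from = "O"
to = "C"
rate = "k_off"
"""


@pytest.fixture
def trimer_params():
    return TrimerParams(
        b_on=6.0, b_off=100.0, r_on=50.0, r_off=200.0,
        RB=5.0, BR=1.5, RB_bon=3.0, BR_bon=0.8, RB_ron=10.0, BR_ron=1.2,
    )


@pytest.fixture
def three_state_scheme():
    return scheme_from_config(THREE_STATE_CFG)


@pytest.fixture
def two_state_scheme():
    return scheme_from_config(TWO_STATE_CFG)


@pytest.fixture
def pulse_protocol():
    return Protocol(
        epochs=(
            Epoch(0.0, 0.02, 0.0),
            Epoch(0.02, 0.002, 1000.0),
            Epoch(0.022, 0.05, 0.0),
        ),
        sampling_rate=10_000.0,
    )


@pytest.fixture
def obs_small():
    return ObservationParams(gamma=1.0, i0=0.0, N_ch=100, eps2=1e-4, nu2=0.0)


def random_trimer_params(rng: np.random.Generator) -> TrimerParams:
    def draw(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    return TrimerParams(
        b_on=draw(0.1, 50), b_off=draw(10, 1000), r_on=draw(1, 500), r_off=draw(1, 500),
        RB=draw(0.2, 20), BR=draw(0.2, 20), RB_bon=draw(0.2, 20), BR_bon=draw(0.2, 20),
        RB_ron=draw(0.2, 20), BR_ron=draw(0.2, 20),
    )
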