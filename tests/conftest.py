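import numpy as np
import pytest

from switchnet import am_protocol, expand, initial_state, library
from switchnet.morphism import parse_node_map

#: Node-level species maps of the bundled emulations onto AM.
BUNDLED_MAPS = {
    "MI": "y -> x\n~z -> x",
    "SI": "spbO -> x\nspbN -> x",
    "GW": "cdk -> x\ncdc25 -> x\n~wee1 -> x\n~pp -> x",
    "EPI": "nuc -> x",
}

#: Best-effort CC map: the clamped inputs a, i have no admissible image.
CC_MAP = "cdk -> x\ncdc25 -> x\n~wee1 -> x"


@pytest.fixture(scope="session")
def am_inet():
    return library("AM")


@pytest.fixture(scope="session")
def am_net(am_inet):
    return expand(am_inet)


@pytest.fixture(scope="session")
def am_rules():
    return am_protocol()


@pytest.fixture(scope="session")
def bundled_morphism_inputs(am_inet, am_net):
    """(model id, source inet, source net, species map) for each bundled map."""
    out = []
    for mid, text in BUNDLED_MAPS.items():
        src = library(mid)
        out.append((mid, src, expand(src), parse_node_map(text, src, am_inet)))
    return out


def am_state(x0: float, x1: float, x2: float) -> dict:
    return {"x_0": x0, "x_1": x1, "x_2": x2}
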