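import numpy as np
import pytest

from rppacra.model import build_default_model, build_model
from rppacra.rppa import fixture_mapping, fixture_table


@pytest.fixture(scope="session")
def table():
    return fixture_table()


@pytest.fixture(scope="session")
def mapping():
    return fixture_mapping()


@pytest.fixture(scope="session")
def default_model():
    return build_default_model()


def toy_chain_config():
    """Driver receptor R -> terminal X, plus an isolated receptor ISO.

    Used for conditional-robustness recovery tests: the R->X rate constant
    is the planted divergence driver of X's AUC; ISO's parameters are
    structurally disconnected from X.
    """
    return {
        "nodes": [
            {"name": "R", "role": "input-receptor", "initial_active": 1e-3},
            {"name": "X", "role": "kinase"},
            {"name": "ISO", "role": "input-receptor", "initial_active": 1e-3},
        ],
        "edges": [
            {"source": "R", "target": "X", "sign": "activating", "k": 1.0, "K": 0.5},
        ],
        "drives": [
            {"node": "R", "strength": 0.5, "K": 0.5},
            {"node": "ISO", "strength": 0.5, "K": 0.5},
        ],
        "decay": {"default": 0.1},
    }


@pytest.fixture(scope="session")
def toy_chain_model():
    return build_model(toy_chain_config())


@pytest.fixture()
def rng():
    return np.random.default_rng(20261001)
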