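import numpy as np
import pandas as pd
import pytest

from ahntools.model import (
    CellClass,
    NeuronRecord,
    NeuronTable,
    Side,
    SynapseEdge,
)
from ahntools.synth import ConnectomeSpec, gen_connectome


@pytest.fixture
def toy_neurons() -> NeuronTable:
    return NeuronTable([
        NeuronRecord("dn1", CellClass.DN, "DNg02", Side.L),
        NeuronRecord("dn2", CellClass.DN, "DNg02", Side.R),
        NeuronRecord("in1", CellClass.IN, "INx", Side.L),
        NeuronRecord("an1", CellClass.AN, None, Side.L),
        NeuronRecord("mn1", CellClass.MN, "MN_wing", Side.L),
        NeuronRecord("F", CellClass.AN, "MsAHN", Side.L),
        NeuronRecord("orf", CellClass.orphan),
    ])


@pytest.fixture
def toy_edges() -> list[SynapseEdge]:
    return [
        SynapseEdge("dn1", "F", 30),
        SynapseEdge("dn2", "F", 3),
        SynapseEdge("in1", "F", 10),
        SynapseEdge("an1", "F", 10),
        SynapseEdge("orf", "F", 7),
        SynapseEdge("F", "mn1", 5),
    ]


@pytest.fixture(scope="session")
def planted_connectome():
    """Default-spec planted connectome shared across tests (seed 0)."""
    return gen_connectome(ConnectomeSpec(seed=0))


def straight_skeleton_frame(n: int, step: float = 1.0) -> pd.DataFrame:
    return pd.DataFrame({
        "node_id": np.arange(1, n + 1),
        "parent_id": np.r_[-1, np.arange(1, n)],
        "x": np.arange(n) * step,
        "y": np.zeros(n),
        "z": np.zeros(n),
        "radius": np.full(n, 0.1),
    })
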