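import networkx as nx
import numpy as np
import pytest

from cofracnet.elution import ElutionMatrix
from cofracnet.metrics import GoDag
from cofracnet.simulate import SimConfig, simulate_dataset


@pytest.fixture(scope="session")
def noiseless_dataset():
    """Small clean study: 60 proteins, 8 planted complexes, no noise."""
    cfg = SimConfig(
        n_proteins=60,
        n_fractions=30,
        n_complexes=8,
        noise_sd=0.0,
        missing_rate=0.0,
        seed=11,
    )
    return simulate_dataset(cfg)


@pytest.fixture
def toy_dag_is_a():
    """Root with two is_a children: the hand-computable 3-node ontology."""
    g = nx.DiGraph()
    g.add_edge("T1", "R", type="is_a")
    g.add_edge("T2", "R", type="is_a")
    return GoDag(g)


@pytest.fixture
def toy_dag_part_of():
    g = nx.DiGraph()
    g.add_edge("T1", "R", type="part_of")
    g.add_edge("T2", "R", type="part_of")
    return GoDag(g)


@pytest.fixture
def normalized_elution():
    """4-protein, 4-fraction normalized matrix with controlled coelution.

    Max per-fraction products: (a,b) 0.005 and (a,d) exactly 0.01 (below /
    at the coelution rule), (a,c) 0.45 and (c,d) 0.016 (above it).
    0.25 * 0.04 is exact in binary floating point, so the tie is genuine.
    """
    values = np.array(
        [
            [0.25, 0.75, 0.0, 0.0],  # a
            [0.02, 0.00, 0.98, 0.0],  # b
            [0.40, 0.60, 0.0, 0.0],  # c
            [0.04, 0.00, 0.0, 0.96],  # d
        ]
    )
    return ElutionMatrix(
        ["a", "b", "c", "d"], values, original_fractions=4, normalized=True
    )
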