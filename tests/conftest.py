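import numpy as np
import pytest

from brainwalk.io import ConnectivityMatrix
from brainwalk.multilayer import LayerGraph, assemble_multilayer


def matrix_from_edges(n, edges, modality="structural"):
    """Symmetric ConnectivityMatrix from (i, j, w) triples."""
    w = np.zeros((n, n))
    for i, j, wt in edges:
        w[i, j] = w[j, i] = wt
    return ConnectivityMatrix(w, modality)


def layer_from_edges(n, edges, modality="structural"):
    return LayerGraph.from_matrix(matrix_from_edges(n, edges, modality))


TOY_S_EDGES = [
    (0, 1, 1.0), (1, 2, 2.0), (0, 2, 0.5), (2, 3, 1.5),
    (3, 4, 1.0), (4, 5, 2.5), (0, 5, 1.0),
]
TOY_F_EDGES = [
    (0, 1, 0.8), (1, 3, 0.6), (2, 3, 0.9), (1, 4, 0.4),
    (4, 5, 0.7), (0, 3, 0.3), (2, 5, 0.55),
]


@pytest.fixture(scope="session")
def toy_multilayer():
    """6-node two-layer network with hand-specified weights, no isolates."""
    s = layer_from_edges(6, TOY_S_EDGES, "structural")
    f = layer_from_edges(6, TOY_F_EDGES, "functional")
    return assemble_multilayer(s, f, theta=0.5)


@pytest.fixture(scope="session")
def identical_layers_net():
    """Both layers identical: the diffusion must reduce to a plain
    second-order biased walk on that single layer."""
    s = layer_from_edges(6, TOY_S_EDGES, "structural")
    f = layer_from_edges(6, TOY_S_EDGES, "functional")
    return assemble_multilayer(s, f, theta=0.5)
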