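"""Structure-guided two-layer brain network with informativeness coupling.

The structural layer keeps every positive entry of the refined structural
matrix. The functional layer is scale-guided by the structural one: each
node nominates its top ``theta * avg_s`` strongest functional entries
(avg_s = 2|E_s|/n, the structural mean degree) and an undirected edge is
kept if either endpoint nominated it. The two layers are coupled by
directed inter-layer edges between corresponding nodes, weighted by node
informativeness I_i = ln(e + |T_i|), where T_i is the set of i's neighbors
joined by an edge no stronger than the layer's mean edge weight — a node
strongly tied to only a few neighbors is the more informative one.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from brainwalk.io import ConnectivityMatrix


@dataclass
class LayerGraph:
    """Undirected weighted layer over n shared nodes.

    Adjacency is stored per node as parallel arrays of neighbor ids and
    positive weights (ids ascending), plus neighbor sets for O(1) membership
    tests during second-order walks.
    """

    n: int
    modality: str
    neighbors: list[np.ndarray] = field(repr=False)
    weights: list[np.ndarray] = field(repr=False)

    def __post_init__(self) -> None:
        self._nbr_sets = [set(a.tolist()) for a in self.neighbors]

    @classmethod
    def from_matrix(cls, mat: ConnectivityMatrix) -> "LayerGraph":
        w = mat.weights
        n = w.shape[0]
        nbrs, wts = [], []
        for i in range(n):
            idx = np.flatnonzero(w[i] > 0)
            nbrs.append(idx.astype(np.int64))
            wts.append(w[i, idx].astype(float))
        return cls(n, mat.modality, nbrs, wts)

    @property
    def n_edges(self) -> int:
        return sum(len(a) for a in self.neighbors) // 2

    def degree(self, i: int) -> int:
        return len(self.neighbors[i])

    def has_edge(self, i: int, j: int) -> bool:
        return j in self._nbr_sets[i]

    def edge_weight_mean(self) -> float:
        """Mean weight over undirected edges, each counted once."""
        if self.n_edges == 0:
            return 0.0
        total = sum(float(w.sum()) for w in self.weights)
        return total / (2 * self.n_edges)

    def edges(self):
        """Iterate canonical (i, j, w) with i < j."""
        for i in range(self.n):
            for j, w in zip(self.neighbors[i], self.weights[i]):
                if i < j:
                    yield i, int(j), float(w)


@dataclass
class MultilayerNetwork:
    """Two node-aligned layers plus informativeness inter-layer weights.

    ``info_s[i]`` weights the transition *into* the structural layer at node
    i (and ``info_f[i]`` into the functional layer); both are >= 1 since
    ln(e + |T|) >= ln(e) = 1.
    """

    structural: LayerGraph
    functional: LayerGraph
    info_s: np.ndarray
    info_f: np.ndarray
    theta: float
    avg_s: float

    @property
    def n(self) -> int:
        return self.structural.n

    def layer(self, tag: str) -> LayerGraph:
        return self.structural if tag == "s" else self.functional


def build_structural_layer(bw_s: ConnectivityMatrix) -> LayerGraph:
    """Layer with an edge for every strictly positive off-diagonal entry."""
    return LayerGraph.from_matrix(bw_s)


def structural_average_degree(layer: LayerGraph) -> float:
    """avg_s = 2|E|/n for an undirected layer."""
    if layer.n == 0:
        raise ValueError("empty layer")
    return 2.0 * layer.n_edges / layer.n


def _nominations_per_node(w: np.ndarray, k_star: int) -> list[np.ndarray]:
    """Top-k incident entries per node, zero entries never nominated.

    Ties are broken by ascending node index for run-to-run determinism.
    """
    n = w.shape[0]
    out = []
    for i in range(n):
        row = w[i]
        pos = np.flatnonzero(row > 0)
        if len(pos) == 0:
            out.append(pos)
            continue
        # stable sort on descending weight => equal weights keep ascending index
        order = pos[np.argsort(-row[pos], kind="stable")]
        out.append(order[:k_star])
    return out


def functional_k_star(avg_s: float, theta: float) -> int:
    """Per-node nomination budget: round-half-up of theta*avg_s, floor 1."""
    if theta <= 0:
        raise ValueError("theta must be positive")
    return max(1, int(np.floor(theta * avg_s + 0.5)))


def build_functional_layer(
    bw_f: ConnectivityMatrix, avg_s: float, theta: float
) -> LayerGraph:
    """Keep, per node, the k* strongest functional entries; union over nodes.

    k* = max(1, round(theta * avg_s)). An undirected edge enters the layer if
    nominated by either endpoint; weights are copied from the refined matrix.
    """
    w = bw_f.weights
    n = w.shape[0]
    k_star = functional_k_star(avg_s, theta)
    keep = np.zeros_like(w, dtype=bool)
    for i, nominated in enumerate(_nominations_per_node(w, k_star)):
        keep[i, nominated] = True
    keep |= keep.T
    pruned = np.where(keep, w, 0.0)
    return LayerGraph.from_matrix(ConnectivityMatrix(pruned, "functional", list(bw_f.region_labels)))


def weak_neighbor_count(layer: LayerGraph, i: int) -> int:
    """|T_i|: neighbors of i joined by an edge with weight <= layer mean."""
    if layer.degree(i) == 0:
        return 0
    mean_w = layer.edge_weight_mean()
    return int(np.count_nonzero(layer.weights[i] <= mean_w))


def informativeness(layer: LayerGraph) -> np.ndarray:
    """I_i = ln(e + |T_i|) per node; always >= 1."""
    mean_w = layer.edge_weight_mean()
    counts = np.array(
        [np.count_nonzero(w <= mean_w) if len(w) else 0 for w in layer.weights],
        dtype=float,
    )
    return np.log(np.e + counts)


def assemble_multilayer(
    structural: LayerGraph, functional: LayerGraph, theta: float
) -> MultilayerNetwork:
    """Couple the two layers with informativeness inter-layer weights."""
    if structural.n != functional.n:
        raise ValueError(
            f"layer size mismatch: {structural.n} structural vs {functional.n} functional nodes"
        )
    return MultilayerNetwork(
        structural=structural,
        functional=functional,
        info_s=informativeness(structural),
        info_f=informativeness(functional),
        theta=theta,
        avg_s=structural_average_degree(structural),
    )


def build_multilayer(
    bw_s: ConnectivityMatrix, bw_f: ConnectivityMatrix, theta: float = 0.5
) -> MultilayerNetwork:
    """Convenience: structural layer, scale-guided functional layer, coupling."""
    s_layer = build_structural_layer(bw_s)
    avg_s = structural_average_degree(s_layer)
    f_layer = build_functional_layer(bw_f, avg_s, theta)
    return assemble_multilayer(s_layer, f_layer, theta)
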