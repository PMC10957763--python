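"""Informativeness-guided diffusion over the two-layer network.

Each step first chooses the next layer at the current node with probability
proportional to the node's informativeness in each layer
(P(structural) = I_s / (I_s + I_f)), then moves to a neighbor within that
layer. If the edge from the previous to the current node exists in the
chosen layer, the neighbor distribution is the second-order (p, q)-biased
one: mass w/p for returning to the previous node, w for neighbors of the
previous node, w/q for nodes two hops away; otherwise the move is plain
weight-proportional. Sampled node ids are recorded with layer tags
discarded, so each brain region maps to a single representation.

All categorical draws go through alias tables (O(1) per step); tables are
built once per (layer, node) and per (layer, previous, current) directed
edge as they are first needed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from brainwalk.alias import AliasTable
from brainwalk.multilayer import LayerGraph, MultilayerNetwork


@dataclass(frozen=True)
class WalkConfig:
    """Sampling parameters.

    p < 1 favors revisiting the previous node; q > 1 keeps the walk local
    (BFS-like), q < 1 pushes it outward (DFS-like). ``walk_length`` counts
    steps, so a completed walk holds walk_length + 1 node ids.
    """

    p: float = 0.1
    q: float = 1.6
    walk_length: int = 10
    walks_per_node: int = 10
    seed: int | None = None

    def __post_init__(self) -> None:
        if self.p <= 0 or self.q <= 0:
            raise ValueError("p and q must be positive")
        if self.walk_length < 1 or self.walks_per_node < 1:
            raise ValueError("walk_length and walks_per_node must be >= 1")


@dataclass
class WalkCorpus:
    """Node-id sequences produced by the sampler (layer tags discarded)."""

    walks: list[list[int]]
    n_nodes: int

    def __len__(self) -> int:
        return len(self.walks)

    def write(self, path) -> None:
        with open(path, "w") as fh:
            for walk in self.walks:
                fh.write(" ".join(str(v) for v in walk) + "\n")


def layer_choice_probs(info_s_i: float, info_f_i: float) -> tuple[float, float]:
    """Inter-layer transition probabilities at one node."""
    if info_s_i <= 0 or info_f_i <= 0:
        raise ValueError("informativeness must be positive")
    total = info_s_i + info_f_i
    return info_s_i / total, info_f_i / total


def intra_layer_distribution(
    layer: LayerGraph,
    current: int,
    previous: int | None,
    prev_edge_in_layer: bool,
    p: float,
    q: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Normalized next-node distribution over current's neighbors in a layer.

    Returns (neighbor_ids, probabilities). With no usable previous edge the
    distribution is weight-proportional; otherwise second-order biased.
    """
    nbrs = layer.neighbors[current]
    wts = layer.weights[current]
    if len(nbrs) == 0:
        raise ValueError(f"node {current} is isolated in the {layer.modality} layer")
    if previous is None or not prev_edge_in_layer:
        mass = wts.copy()
    else:
        mass = _second_order_mass(layer, previous, current, p, q)
    return nbrs, mass / mass.sum()


def _second_order_mass(
    layer: LayerGraph, previous: int, current: int, p: float, q: float
) -> np.ndarray:
    nbrs = layer.neighbors[current]
    wts = layer.weights[current]
    mass = np.empty(len(nbrs))
    for idx, (x, w) in enumerate(zip(nbrs, wts)):
        if x == previous:
            mass[idx] = w / p
        elif layer.has_edge(previous, int(x)):
            mass[idx] = w
        else:
            mass[idx] = w / q
    return mass


@dataclass
class _AliasCache:
    """Lazily-built alias tables for one multilayer network."""

    net: MultilayerNetwork
    p: float
    q: float
    first_order: dict = field(default_factory=dict)
    second_order: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.s_iso = [self.net.structural.degree(i) == 0 for i in range(self.net.n)]
        self.f_iso = [self.net.functional.degree(i) == 0 for i in range(self.net.n)]

    def first(self, tag: str, node: int) -> AliasTable:
        key = (tag, node)
        tbl = self.first_order.get(key)
        if tbl is None:
            tbl = AliasTable(self.net.layer(tag).weights[node])
            self.first_order[key] = tbl
        return tbl

    def second(self, tag: str, previous: int, current: int) -> AliasTable:
        key = (tag, previous, current)
        tbl = self.second_order.get(key)
        if tbl is None:
            tbl = AliasTable(
                _second_order_mass(self.net.layer(tag), previous, current, self.p, self.q)
            )
            self.second_order[key] = tbl
        return tbl


def _walk(
    net: MultilayerNetwork,
    start: int,
    config: WalkConfig,
    rng: np.random.Generator,
    cache: _AliasCache,
) -> list[int]:
    seq = [start]
    previous: int | None = None
    current = start
    s_iso, f_iso = cache.s_iso, cache.f_iso
    for _ in range(config.walk_length):
        p_s, _ = layer_choice_probs(net.info_s[current], net.info_f[current])
        tag = "s" if rng.random() < p_s else "f"
        if (tag == "s" and s_iso[current]) or (tag == "f" and f_iso[current]):
            tag = "f" if tag == "s" else "s"
            if (tag == "s" and s_iso[current]) or (tag == "f" and f_iso[current]):
                break  # isolated in both layers: the walk ends here
        layer = net.layer(tag)
        if previous is not None and layer.has_edge(previous, current):
            tbl = cache.second(tag, previous, current)
        else:
            tbl = cache.first(tag, current)
        nxt = int(layer.neighbors[current][tbl.draw(rng)])
        seq.append(nxt)
        previous, current = current, nxt
    return seq


def simulate_walk(
    net: MultilayerNetwork,
    start: int,
    config: WalkConfig,
    rng: np.random.Generator,
    cache: _AliasCache | None = None,
) -> list[int]:
    """One diffusion walk from ``start``; at most walk_length + 1 node ids.

    A node isolated in both layers terminates the walk early (a length-1
    walk from such a start is valid).
    """
    if not 0 <= start < net.n:
        raise ValueError(f"start node {start} out of range [0, {net.n})")
    if cache is None:
        cache = _AliasCache(net, config.p, config.q)
    return _walk(net, start, config, rng, cache)


def generate_corpus(net: MultilayerNetwork, config: WalkConfig) -> WalkCorpus:
    """r walks from every node, start order shuffled per repetition.

    Fully reproducible given ``config.seed``.
    """
    rng = np.random.default_rng(config.seed)
    cache = _AliasCache(net, config.p, config.q)
    walks = []
    for _ in range(config.walks_per_node):
        for start in rng.permutation(net.n):
            walks.append(_walk(net, int(start), config, rng, cache))
    return WalkCorpus(walks, net.n)
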