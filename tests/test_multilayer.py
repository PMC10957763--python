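import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainwalk.io import ConnectivityMatrix
from brainwalk.multilayer import (
    LayerGraph,
    assemble_multilayer,
    build_functional_layer,
    build_structural_layer,
    functional_k_star,
    informativeness,
    structural_average_degree,
    weak_neighbor_count,
)

from conftest import layer_from_edges, matrix_from_edges


class TestStructuralLayer:
    def test_edge_count_matches_positive_entries(self):
        m = matrix_from_edges(5, [(0, 1, 1.0), (1, 2, 0.5), (2, 3, 2.0), (0, 4, 0.1)])
        layer = build_structural_layer(m)
        assert layer.n_edges == 4

    def test_all_zero_gives_empty_layer(self):
        layer = build_structural_layer(ConnectivityMatrix(np.zeros((4, 4)), "structural"))
        assert layer.n_edges == 0

    def test_weight_passthrough(self):
        layer = build_structural_layer(matrix_from_edges(3, [(0, 2, 1.62)]))
        assert layer.has_edge(0, 2)
        assert layer.weights[0][list(layer.neighbors[0]).index(2)] == 1.62


class TestAverageDegree:
    @pytest.mark.parametrize(
        "n,edges,expected",
        [
            (4, [(0, 1, 1), (1, 2, 1), (2, 3, 1)], 1.5),
            (4, [], 0.0),
        ],
    )
    def test_formula(self, n, edges, expected):
        assert structural_average_degree(layer_from_edges(n, edges)) == expected

    def test_ninety_node_case(self):
        # avg_s = 2|E|/n: 2*360/90 = 8
        rng = np.random.default_rng(0)
        edges = set()
        while len(edges) < 360:
            i, j = sorted(rng.integers(0, 90, 2))
            if i != j:
                edges.add((int(i), int(j)))
        layer = layer_from_edges(90, [(i, j, 1.0) for i, j in edges])
        assert structural_average_degree(layer) == 8.0


class TestFunctionalLayer:
    def test_nomination_budget(self):
        assert functional_k_star(8.0, 0.5) == 4
        assert functional_k_star(0.4, 0.5) == 1  # floor of one nomination
        assert functional_k_star(7.0, 0.5) == 4  # round half up of 3.5

    def test_zero_entries_never_nominated(self):
        w = np.zeros((4, 4))
        w[0, 1] = w[1, 0] = 0.5
        layer = build_functional_layer(ConnectivityMatrix(w, "functional"), 8.0, 0.5)
        assert layer.n_edges == 1  # nodes 2,3 contribute nothing

    def test_union_of_argmax_nominations(self):
        # dense 4-node matrix, distinct weights, k*=1: brute-force the
        # per-node argmax nominations and their union
        w = np.array(
            [
                [0, 0.9, 0.2, 0.3],
                [0.9, 0, 0.4, 0.1],
                [0.2, 0.4, 0, 0.8],
                [0.3, 0.1, 0.8, 0],
            ]
        )
        expected = set()
        for i in range(4):
            j = int(np.argmax(w[i]))
            expected.add((min(i, j), max(i, j)))
        layer = build_functional_layer(ConnectivityMatrix(w, "functional"), 2.0, 0.5)
        got = {(i, j) for i, j, _ in layer.edges()}
        assert got == expected
        assert 2 <= layer.n_edges <= 4

    def test_per_node_degree_bound(self):
        rng = np.random.default_rng(1)
        w = rng.random((12, 12))
        w = np.triu(w, 1)
        w = w + w.T
        k_star = 3
        layer = build_functional_layer(
            ConnectivityMatrix(w, "functional"), avg_s=6.0, theta=0.5
        )
        # degree of a node <= own nominations + nominations received
        for i in range(12):
            assert layer.degree(i) <= k_star + 11


class TestInformativeness:
    def test_weak_neighbor_count_against_layer_mean(self):
        # edges at node 0: weights 0.1, 0.2, 0.9; layer mean = 0.4
        layer = layer_from_edges(4, [(0, 1, 0.1), (0, 2, 0.2), (0, 3, 0.9)])
        assert weak_neighbor_count(layer, 0) == 2

    def test_isolated_node_has_no_weak_neighbors(self):
        layer = layer_from_edges(3, [(0, 1, 1.0)])
        assert weak_neighbor_count(layer, 2) == 0

    def test_equal_weights_make_every_neighbor_weak(self):
        layer = layer_from_edges(4, [(0, 1, 0.3), (1, 2, 0.3), (2, 3, 0.3), (3, 0, 0.3)])
        for i in range(4):
            assert weak_neighbor_count(layer, i) == layer.degree(i)

    @pytest.mark.parametrize(
        "count,expected",
        [(0, 1.0), (2, 1.5514447139320509), (3, 1.743668380628679)],
    )
    def test_log_informativeness_values(self, count, expected):
        assert math.log(math.e + count) == pytest.approx(expected, abs=1e-12)

    def test_informativeness_vector(self):
        layer = layer_from_edges(4, [(0, 1, 0.1), (0, 2, 0.2), (0, 3, 0.9)])
        info = informativeness(layer)
        # node 0: two weak neighbors; nodes 1,2: their single edge is weak;
        # node 3: edge weight 0.9 > mean 0.4, no weak neighbors
        np.testing.assert_allclose(
            info,
            [math.log(math.e + 2), math.log(math.e + 1), math.log(math.e + 1), 1.0],
        )
        assert (info >= 1.0).all()

    @given(seed=st.integers(0, 1000))
    @settings(deadline=None, max_examples=20)
    def test_permutation_equivariance(self, seed):
        rng = np.random.default_rng(seed)
        w = rng.random((7, 7)) * (rng.random((7, 7)) < 0.6)
        w = np.triu(w, 1)
        w = w + w.T
        perm = rng.permutation(7)
        info = informativeness(LayerGraph.from_matrix(ConnectivityMatrix(w, "structural")))
        wp = w[np.ix_(perm, perm)]
        info_p = informativeness(
            LayerGraph.from_matrix(ConnectivityMatrix(wp, "structural"))
        )
        np.testing.assert_allclose(info_p, info[perm], atol=1e-12)


class TestAssemble:
    def test_identical_layers_have_identical_info(self, identical_layers_net):
        np.testing.assert_allclose(
            identical_layers_net.info_s, identical_layers_net.info_f
        )

    def test_empty_structural_layer_info_is_one(self):
        s = layer_from_edges(4, [])
        f = layer_from_edges(4, [(0, 1, 0.5)], "functional")
        net = assemble_multilayer(s, f, theta=0.5)
        np.testing.assert_array_equal(net.info_s, np.ones(4))

    def test_size_mismatch_rejected(self):
        with pytest.raises(ValueError, match="mismatch"):
            assemble_multilayer(
                layer_from_edges(4, []), layer_from_edges(5, [], "functional"), 0.5
            )

    def test_toy_info_matches_brute_force(self, toy_multilayer):
        net = toy_multilayer
        for layer, info in ((net.structural, net.info_s), (net.functional, net.info_f)):
            mean_w = layer.edge_weight_mean()
            for i in range(net.n):
                weak = sum(
                    1 for w in layer.weights[i] if w <= mean_w
                )
                assert info[i] == pytest.approx(math.log(math.e + weak))
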