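import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from brainwalk.distances import (
    NodeTemplate,
    ReconfiguredMatrix,
    build_network_templates,
    build_node_template,
    concatenate_network,
    cosine_distance,
    network_distance_matrix,
    node_distance_matrix,
    pca_reconfigure,
)


def _rand_recon(rng, n=4, k=3):
    return ReconfiguredMatrix(rng.standard_normal((n, k)), np.zeros(k))


class TestPCA:
    def test_rank_one_input(self):
        v = np.array([1.0, -2.0, 0.5, 3.0])
        F = np.outer([1.0, 2.0, 3.0, 4.0, 5.0], v)
        rec = pca_reconfigure(F, k=2)
        total = rec.explained_variance.sum()
        assert rec.explained_variance[0] / total == pytest.approx(1.0)
        assert np.abs(rec.A[:, 1]).max() < 1e-10

    def test_variance_ordering_and_bound(self):
        rng = np.random.default_rng(0)
        F = rng.standard_normal((20, 10))
        rec = pca_reconfigure(F, k=6)
        assert np.all(np.diff(rec.explained_variance) <= 1e-12)
        total_var = np.var(F, axis=0, ddof=1).sum()
        assert rec.explained_variance.sum() <= total_var + 1e-9
        # retained variance grows with k
        prev = 0.0
        for k in (2, 4, 6):
            s = pca_reconfigure(F, k=k).explained_variance.sum()
            assert s >= prev
            prev = s

    def test_scores_match_eigendecomposition_oracle(self):
        rng = np.random.default_rng(1)
        F = rng.standard_normal((10, 6))
        rec = pca_reconfigure(F, k=3)
        X = F - F.mean(axis=0)
        cov = X.T @ X / (10 - 1)
        evals, evecs = np.linalg.eigh(cov)
        order = np.argsort(evals)[::-1][:3]
        scores = X @ evecs[:, order]
        for col in range(3):
            got, exp = rec.A[:, col], scores[:, col]
            agree = np.allclose(got, exp, atol=1e-9) or np.allclose(got, -exp, atol=1e-9)
            assert agree
        np.testing.assert_allclose(rec.explained_variance, evals[order], atol=1e-9)

    def test_sign_convention_is_subject_invariant(self):
        # two noisy observations of the same structure orient identically
        rng = np.random.default_rng(2)
        base = np.vstack([np.repeat([3.0, -1.0], 5), np.tile([1.0, -1.0], 5)]).T
        for _ in range(5):
            Q1, _ = np.linalg.qr(rng.standard_normal((8, 8)))
            Q2, _ = np.linalg.qr(rng.standard_normal((8, 8)))
            F1 = base @ rng.standard_normal((2, 8)) @ Q1
            F2 = (base + 0.05 * rng.standard_normal(base.shape)) @ rng.standard_normal((2, 8)) @ Q2
            a1 = pca_reconfigure(F1, k=2).A
            a2 = pca_reconfigure(F2, k=2).A
            assert np.corrcoef(a1[:, 0], a2[:, 0])[0, 1] > 0

    def test_k_validation(self):
        F = np.random.default_rng(0).standard_normal((5, 4))
        with pytest.raises(ValueError):
            pca_reconfigure(F, k=4)
        with pytest.raises(ValueError):
            pca_reconfigure(F, k=0)
        with pytest.warns(UserWarning, match="capping"):
            rec = pca_reconfigure(np.random.default_rng(0).standard_normal((3, 10)), k=5)
        assert rec.k == 2


class TestCosineDistance:
    @pytest.mark.parametrize(
        "a,b,expected",
        [
            ((1, 1), (1, 1), 0.0),
            ((1, 0), (0, 1), 1.0),
            ((1, 0), (-1, 0), 2.0),
        ],
    )
    def test_reference_values(self, a, b, expected):
        assert cosine_distance(np.array(a, float), np.array(b, float)) == pytest.approx(expected)

    def test_zero_vector_rejected(self):
        with pytest.raises(ValueError):
            cosine_distance(np.zeros(3), np.ones(3))

    @given(st.integers(0, 10_000))
    @settings(deadline=None, max_examples=50)
    def test_bounds_and_symmetry(self, seed):
        rng = np.random.default_rng(seed)
        a, b = rng.standard_normal(5), rng.standard_normal(5)
        d = cosine_distance(a, b)
        assert 0.0 <= d <= 2.0
        assert d == pytest.approx(cosine_distance(b, a))
        assert cosine_distance(a, a) == pytest.approx(0.0, abs=1e-12)


class TestNodeTemplates:
    def test_single_subject_template(self):
        rng = np.random.default_rng(0)
        m = _rand_recon(rng)
        t = build_node_template([m], "g")
        np.testing.assert_array_equal(t.tau, m.A)
        assert t.support == 1

    def test_opposite_rows_cancel(self):
        a = _rand_recon(np.random.default_rng(1))
        b = ReconfiguredMatrix(-a.A, np.zeros(a.k))
        t = build_node_template([a, b])
        np.testing.assert_allclose(t.tau, 0, atol=1e-15)

    def test_mean_oracle(self):
        rng = np.random.default_rng(2)
        mats = [_rand_recon(rng) for _ in range(3)]
        t = build_node_template(mats)
        for i in range(4):
            expected = np.mean([m.A[i] for m in mats], axis=0)
            np.testing.assert_allclose(t.tau[i], expected)

    def test_empty_and_mismatched_groups_rejected(self):
        with pytest.raises(ValueError):
            build_node_template([])
        rng = np.random.default_rng(3)
        with pytest.raises(ValueError):
            build_node_template([_rand_recon(rng, 4, 3), _rand_recon(rng, 4, 2)])


class TestNodeDistances:
    def test_subject_equal_to_template_is_zero(self):
        rng = np.random.default_rng(0)
        m = _rand_recon(rng)
        t = NodeTemplate(m.A.copy(), "g", 3)
        L = node_distance_matrix([m], t)
        np.testing.assert_allclose(L, 0, atol=1e-12)

    def test_orthogonal_rows_give_ones(self):
        m = ReconfiguredMatrix(np.tile([1.0, 0.0], (4, 1)), np.zeros(2))
        t = NodeTemplate(np.tile([0.0, 1.0], (4, 1)), "g", 2)
        np.testing.assert_allclose(node_distance_matrix([m], t), 1.0)

    def test_entrywise_oracle(self):
        rng = np.random.default_rng(1)
        subs = [_rand_recon(rng) for _ in range(3)]
        t = build_node_template(subs[:2])
        L = node_distance_matrix(subs, t)
        for r, s in enumerate(subs):
            for i in range(4):
                u, v = s.A[i], t.tau[i]
                expected = 1 - u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
                assert L[r, i] == pytest.approx(expected)

    def test_leave_one_out_members(self):
        rng = np.random.default_rng(2)
        a, b = _rand_recon(rng), _rand_recon(rng)
        t = build_node_template([a, b])
        L = node_distance_matrix([a, b], t, member_indices=[0, 1])
        # each member is compared against the other subject's rows only
        for i in range(4):
            u, v = a.A[i], b.A[i]
            expected = 1 - u @ v / (np.linalg.norm(u) * np.linalg.norm(v))
            assert L[0, i] == pytest.approx(expected)
            assert L[1, i] == pytest.approx(expected)

    def test_zero_row_records_maximum_with_warning(self):
        m = ReconfiguredMatrix(np.zeros((2, 3)), np.zeros(3))
        t = NodeTemplate(np.ones((2, 3)), "g", 1)
        with pytest.warns(UserWarning, match="zero vector"):
            L = node_distance_matrix([m], t)
        np.testing.assert_array_equal(L, 2.0)


class TestNetworkDistances:
    def test_row_major_concatenation(self):
        m = ReconfiguredMatrix(np.array([[1.0, 2.0], [3.0, 4.0]]), np.zeros(2))
        np.testing.assert_array_equal(concatenate_network(m), [1, 2, 3, 4])

    def test_single_subject_template(self):
        rng = np.random.default_rng(0)
        a, b = _rand_recon(rng), _rand_recon(rng)
        c_plus, c_minus = build_network_templates([a], [b])
        np.testing.assert_array_equal(c_plus, concatenate_network(a))
        np.testing.assert_array_equal(c_minus, concatenate_network(b))

    def test_subject_identical_to_positive_template(self):
        rng = np.random.default_rng(1)
        a, b = _rand_recon(rng), _rand_recon(rng)
        c_plus, c_minus = build_network_templates([a], [b])
        H = network_distance_matrix([a], c_plus, c_minus)
        assert H[0, 0] == pytest.approx(0.0, abs=1e-12)
        assert H[0, 1] == pytest.approx(cosine_distance(c_plus, c_minus))

    def test_antipodal_templates(self):
        rng = np.random.default_rng(2)
        a = _rand_recon(rng)
        c_plus = concatenate_network(a)
        H = network_distance_matrix([a], c_plus, -c_plus)
        np.testing.assert_allclose(H[0], [0.0, 2.0], atol=1e-12)

    def test_group_mean_oracle(self):
        rng = np.random.default_rng(3)
        pos = [_rand_recon(rng) for _ in range(3)]
        neg = [_rand_recon(rng) for _ in range(2)]
        c_plus, c_minus = build_network_templates(pos, neg)
        np.testing.assert_allclose(
            c_plus, np.mean([concatenate_network(m) for m in pos], axis=0)
        )
        np.testing.assert_allclose(
            c_minus, np.mean([concatenate_network(m) for m in neg], axis=0)
        )

    def test_zero_template_rejected(self):
        rng = np.random.default_rng(4)
        a = _rand_recon(rng)
        with pytest.raises(ValueError):
            network_distance_matrix([a], np.zeros(12), np.ones(12))
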