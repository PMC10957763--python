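"""PCA reconfiguration, group templates, and cosine distances.

A given embedding dimension can encode different latent concepts in
different subjects, so each subject's n x d representation is reconfigured
by its own PCA into n x k scores ordered by explained variance before any
cross-subject comparison. Group centroids then serve as shared reference
coordinates: per-node templates tau_i for region-level distances, and
concatenated-network templates C+/C- for subject-level distances.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from sklearn.decomposition import PCA

from brainwalk.embedding import EmbeddingMatrix

#: seed of the frozen reference sequence used to orient principal components
_SIGN_REFERENCE_SEED = 12345


@dataclass
class ReconfiguredMatrix:
    """n x k PCA scores of one subject, columns ordered by variance."""

    A: np.ndarray
    explained_variance: np.ndarray

    @property
    def n(self) -> int:
        return self.A.shape[0]

    @property
    def k(self) -> int:
        return self.A.shape[1]


@dataclass
class NodeTemplate:
    """Per-node centroid representations of one group."""

    tau: np.ndarray
    group_label: str
    support: int


def pca_reconfigure(F: EmbeddingMatrix | np.ndarray, k: int) -> ReconfiguredMatrix:
    """Project a subject's node representations onto its top-k principal axes.

    Rows (nodes) are the samples; the embedding dimensions are centered over
    nodes. At most min(n - 1, d) components exist; a larger request is capped
    with a warning. Each component's loading vector is flipped so that its
    largest-magnitude entry is positive, removing the eigenvector sign
    ambiguity that would otherwise scramble cross-subject templates.
    """
    X = F.F if isinstance(F, EmbeddingMatrix) else np.asarray(F, dtype=float)
    n, d = X.shape
    if n < 2:
        raise ValueError("PCA needs at least 2 nodes")
    if k >= d:
        raise ValueError(f"k must be < d ({d}), got {k}")
    if k < 1:
        raise ValueError("k must be >= 1")
    avail = min(n - 1, d)
    if k > avail:
        warnings.warn(f"only {avail} principal components available; capping k={k}")
        k = avail
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(X)
    # Deterministic sign fixed in the shared node space: each score column is
    # flipped so its projection onto a fixed reference vector (a frozen
    # pseudorandom sequence over node ids, identical for every subject) is
    # positive. Loadings live in the subject-specific embedding basis and
    # cannot give a convention that is consistent across subjects; score
    # columns are indexed by the shared nodes, so any fixed reference orients
    # structured components identically in every subject.
    ref = np.random.default_rng(_SIGN_REFERENCE_SEED).standard_normal(n)
    flip = np.sign(ref @ scores)
    flip[flip == 0] = 1.0
    scores = scores * flip
    return ReconfiguredMatrix(A=scores, explained_variance=pca.explained_variance_.copy())


def cosine_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - cos(a, b); 0 for parallel, 1 orthogonal, 2 anti-parallel."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na = np.linalg.norm(a)
    nb = np.linalg.norm(b)
    if na == 0 or nb == 0:
        raise ValueError("cosine distance undefined for a zero vector")
    return float(np.clip(1.0 - (a @ b) / (na * nb), 0.0, 2.0))


def _check_shapes(mats: list[ReconfiguredMatrix]) -> tuple[int, int]:
    if not mats:
        raise ValueError("empty group")
    n, k = mats[0].n, mats[0].k
    for m in mats:
        if (m.n, m.k) != (n, k):
            raise ValueError("reconfigured matrices have mismatched shapes")
    return n, k


def build_node_template(
    group_matrices: list[ReconfiguredMatrix], group_label: str = ""
) -> NodeTemplate:
    """tau_i = mean over the group of each subject's node-i row."""
    _check_shapes(group_matrices)
    stack = np.stack([m.A for m in group_matrices])
    return NodeTemplate(
        tau=stack.mean(axis=0), group_label=group_label, support=len(group_matrices)
    )


def _safe_row_distance(u: np.ndarray, v: np.ndarray) -> float:
    # zero operand inside a cohort loop: record the maximum rather than abort
    if np.linalg.norm(u) == 0 or np.linalg.norm(v) == 0:
        warnings.warn("zero vector in node distance; recording maximum distance 2")
        return 2.0
    return cosine_distance(u, v)


def node_distance_matrix(
    subjects: list[ReconfiguredMatrix],
    template: NodeTemplate,
    member_indices: list[int] | None = None,
    member_matrices: list[ReconfiguredMatrix] | None = None,
) -> np.ndarray:
    """m x n matrix of cosine distances to the per-node template.

    ``L[r, i]`` is the distance between subject r's node-i row and tau_i.
    If ``member_indices`` lists subjects that belong to the template's own
    group (with ``member_matrices`` the full group used to build it), each
    such subject is compared against the jackknifed centroid that excludes
    it: a subject inside its own centroid is biased toward it, which would
    distort between-group statistics.
    """
    n, k = _check_shapes(subjects)
    if template.tau.shape != (n, k):
        raise ValueError("template shape does not match subjects")
    loo: dict[int, np.ndarray] = {}
    if member_indices:
        if template.support < 2:
            raise ValueError("leave-one-out needs a template built from >= 2 subjects")
        m = template.support
        for subj_idx in member_indices:
            own = subjects[subj_idx].A
            loo[subj_idx] = (m * template.tau - own) / (m - 1)
    L = np.empty((len(subjects), n))
    for r, subj in enumerate(subjects):
        tau = loo.get(r, template.tau)
        for i in range(n):
            L[r, i] = _safe_row_distance(subj.A[i], tau[i])
    return L


def concatenate_network(mat: ReconfiguredMatrix) -> np.ndarray:
    """Row-major flattening of A into a length n*k network representation."""
    return mat.A.reshape(-1)


def build_network_templates(
    positive: list[ReconfiguredMatrix], negative: list[ReconfiguredMatrix]
) -> tuple[np.ndarray, np.ndarray]:
    """Group means of concatenated network representations (C+, C-)."""
    _check_shapes(positive)
    _check_shapes(negative)
    c_plus = np.mean([concatenate_network(m) for m in positive], axis=0)
    c_minus = np.mean([concatenate_network(m) for m in negative], axis=0)
    return c_plus, c_minus


def network_distance_matrix(
    subjects: list[ReconfiguredMatrix], c_plus: np.ndarray, c_minus: np.ndarray
) -> np.ndarray:
    """m x 2 distances of each subject's concatenated A to C+ and C-."""
    if np.linalg.norm(c_plus) == 0 or np.linalg.norm(c_minus) == 0:
        raise ValueError("zero network template")
    H = np.empty((len(subjects), 2))
    for r, subj in enumerate(subjects):
        a = concatenate_network(subj)
        H[r, 0] = _safe_row_distance(a, c_plus)
        H[r, 1] = _safe_row_distance(a, c_minus)
    return H
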