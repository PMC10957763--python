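"""Skip-gram node representations learned from the walk corpus.

The objective maximizes the log-probability of each node's walk context
given its vector, sum_v sum_{u in N(v)} [F(u).F(v) - log Z_v], with the
partition function Z_v estimated by negative sampling and optimized by
stochastic gradient ascent. Context predictions factorize into per-pair
terms (conditional independence), and input/output roles are symmetric in
form; the input vectors are returned as the representation.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from brainwalk._sgns import train_kernel
from brainwalk.alias import AliasTable
from brainwalk.diffusion import WalkCorpus

#: unigram exponent of the negative-sampling noise distribution
NOISE_POWER = 0.75


@dataclass
class EmbeddingMatrix:
    """n x d node representations; ``context`` holds the output vectors."""

    F: np.ndarray
    context: np.ndarray

    @property
    def n_nodes(self) -> int:
        return self.F.shape[0]

    @property
    def d(self) -> int:
        return self.F.shape[1]

    def write(self, path, labels: list[str] | None = None) -> None:
        labels = labels or [str(i) for i in range(self.n_nodes)]
        with open(path, "w") as fh:
            for lab, row in zip(labels, self.F):
                fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def _flatten(corpus: WalkCorpus) -> tuple[np.ndarray, np.ndarray]:
    offsets = np.zeros(len(corpus.walks) + 1, dtype=np.int64)
    for i, w in enumerate(corpus.walks):
        offsets[i + 1] = offsets[i] + len(w)
    tokens = np.empty(offsets[-1], dtype=np.int64)
    for i, w in enumerate(corpus.walks):
        tokens[offsets[i] : offsets[i + 1]] = w
    return tokens, offsets


def noise_distribution(corpus: WalkCorpus) -> np.ndarray:
    """Unigram frequency raised to 3/4, normalized over all node ids."""
    counts = np.bincount(
        np.concatenate([np.asarray(w) for w in corpus.walks]), minlength=corpus.n_nodes
    ).astype(float)
    noise = counts**NOISE_POWER
    return noise / noise.sum()


def train_embeddings(
    corpus: WalkCorpus,
    d: int = 80,
    window: int = 10,
    negatives: int = 5,
    epochs: int = 5,
    seed: int = 0,
    lr: float = 0.025,
    lr_min: float = 1e-4,
) -> EmbeddingMatrix:
    """Train n x d representations from the corpus.

    Single-threaded and bit-reproducible for a fixed seed. Every node id in
    [0, n) must occur in the corpus (guaranteed when the corpus starts r
    walks from every node).
    """
    if not corpus.walks:
        raise ValueError("empty walk corpus")
    tokens, offsets = _flatten(corpus)
    present = np.bincount(tokens, minlength=corpus.n_nodes) > 0
    if not present.all():
        raise AssertionError(
            f"node(s) {np.flatnonzero(~present).tolist()} absent from corpus"
        )
    noise = noise_distribution(corpus)
    table = AliasTable(noise)
    init_rng = np.random.default_rng(seed)
    syn0 = (init_rng.random((corpus.n_nodes, d)) - 0.5) / d
    syn1 = np.zeros((corpus.n_nodes, d))
    train_kernel(
        tokens,
        offsets,
        syn0,
        syn1,
        int(window),
        int(negatives),
        int(epochs),
        float(lr),
        float(lr_min),
        table.prob,
        table.alias,
        np.uint64(seed * 2 + 1),
    )
    return EmbeddingMatrix(F=syn0, context=syn1)


def negative_sampling_loss(
    corpus: WalkCorpus,
    emb: EmbeddingMatrix,
    window: int = 10,
    negatives: int = 5,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the (negated) training objective.

    Mean over center-context pairs of -log sigma(F(c).F'(u))
    - sum_neg log sigma(-F(c).F'(neg)); lower is better. Used to check that
    training ascends the objective on a fixed corpus.
    """
    rng = np.random.default_rng(seed)
    noise = noise_distribution(corpus)
    total, pairs = 0.0, 0
    for walk in corpus.walks:
        L = len(walk)
        for pos, center in enumerate(walk):
            for cpos in range(max(0, pos - window), min(L, pos + window + 1)):
                if cpos == pos:
                    continue
                ctx = walk[cpos]
                f = float(emb.F[center] @ emb.context[ctx])
                total += float(np.logaddexp(0.0, -f))
                negs = rng.choice(corpus.n_nodes, size=negatives, p=noise)
                fn = emb.F[center] @ emb.context[negs].T
                total += float(np.logaddexp(0.0, fn).sum())
                pairs += 1
    return total / max(pairs, 1)
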