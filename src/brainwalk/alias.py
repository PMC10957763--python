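"""Walker's alias method for O(1) sampling from discrete distributions.

Table construction is O(K); each draw consumes exactly two uniforms
regardless of K, which keeps every diffusion step constant-time.
"""

from __future__ import annotations

import numpy as np


class AliasTable:
    """Alias table over a finite nonnegative weight vector."""

    __slots__ = ("prob", "alias", "k")

    def __init__(self, weights: np.ndarray) -> None:
        w = np.asarray(weights, dtype=float)
        if w.ndim != 1 or len(w) == 0:
            raise ValueError("need a nonempty 1-D weight vector")
        if (w < 0).any():
            raise ValueError("weights must be nonnegative")
        total = w.sum()
        if total <= 0:
            raise ValueError("weights must have positive sum")
        k = len(w)
        scaled = w * (k / total)
        prob = np.empty(k)
        alias = np.zeros(k, dtype=np.int64)
        small = [i for i in range(k) if scaled[i] < 1.0]
        large = [i for i in range(k) if scaled[i] >= 1.0]
        while small and large:
            s = small.pop()
            l = large.pop()
            prob[s] = scaled[s]
            alias[s] = l
            scaled[l] = scaled[l] - (1.0 - scaled[s])
            (small if scaled[l] < 1.0 else large).append(l)
        for i in large:
            prob[i] = 1.0
        for i in small:  # numerical leftovers
            prob[i] = 1.0
        self.prob = prob
        self.alias = alias
        self.k = k

    def draw(self, rng: np.random.Generator) -> int:
        """Sample one index; consumes exactly 2 uniforms."""
        i = int(rng.random() * self.k)
        if i == self.k:  # guard the measure-zero u == 1.0 edge
            i -= 1
        return i if rng.random() < self.prob[i] else int(self.alias[i])

    def probabilities(self) -> np.ndarray:
        """Reconstruct the normalized distribution encoded by the table."""
        p = np.zeros(self.k)
        for i in range(self.k):
            p[i] += self.prob[i]
            p[self.alias[i]] += 1.0 - self.prob[i]
        return p / self.k
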