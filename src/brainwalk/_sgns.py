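"""Numba kernel for skip-gram training with negative sampling.

The kernel owns its RNG (xorshift64*) so training is bit-reproducible for a
given seed, independent of NumPy global state and thread count (the kernel
is single-threaded by design).
"""

from __future__ import annotations

import numpy as np
from numba import njit

_MULT = np.uint64(2685821657736338717)
_INV53 = 1.0 / (1 << 53)


@njit(cache=True, inline="always")
def _next(state):
    x = state
    x ^= x >> np.uint64(12)
    x ^= x << np.uint64(25)
    x ^= x >> np.uint64(27)
    return x


@njit(cache=True, inline="always")
def _uniform(x):
    return float((x * _MULT) >> np.uint64(11)) * _INV53


@njit(cache=True)
def train_kernel(
    tokens,      # int64[:] all walks concatenated
    offsets,     # int64[:] walk w spans tokens[offsets[w]:offsets[w+1]]
    syn0,        # float64[n, d] input vectors, updated in place
    syn1,        # float64[n, d] output vectors, updated in place
    window,      # int
    negatives,   # int
    epochs,      # int
    lr0,         # float initial learning rate
    lr_min,      # float floor for the linear decay
    neg_prob,    # float64[n] alias probabilities of the noise distribution
    neg_alias,   # int64[n] alias indices
    seed,        # uint64
):
    d = syn0.shape[1]
    k = neg_prob.shape[0]
    state = np.uint64(seed) * _MULT + np.uint64(1)
    total_tokens = tokens.shape[0] * epochs
    processed = 0
    grad = np.empty(d)
    for _ in range(epochs):
        for w in range(offsets.shape[0] - 1):
            lo = offsets[w]
            hi = offsets[w + 1]
            for pos in range(lo, hi):
                center = tokens[pos]
                lr = lr0 * (1.0 - processed / (total_tokens + 1.0))
                if lr < lr_min:
                    lr = lr_min
                processed += 1
                # shrink the window uniformly, as in the original skip-gram
                state = _next(state)
                b = int((state * _MULT) >> np.uint64(32)) % window
                win = window - b
                start = pos - win
                if start < lo:
                    start = lo
                stop = pos + win + 1
                if stop > hi:
                    stop = hi
                for cpos in range(start, stop):
                    if cpos == pos:
                        continue
                    ctx = tokens[cpos]
                    for j in range(d):
                        grad[j] = 0.0
                    h = syn0[center]
                    for neg in range(negatives + 1):
                        if neg == 0:
                            target = ctx
                            label = 1.0
                        else:
                            state = _next(state)
                            u1 = _uniform(state)
                            state = _next(state)
                            u2 = _uniform(state)
                            i = int(u1 * k)
                            if i >= k:
                                i = k - 1
                            target = i if u2 < neg_prob[i] else neg_alias[i]
                            if target == ctx:
                                continue
                            label = 0.0
                        f = 0.0
                        for j in range(d):
                            f += h[j] * syn1[target, j]
                        if f > 8.0:
                            sig = 1.0
                        elif f < -8.0:
                            sig = 0.0
                        else:
                            sig = 1.0 / (1.0 + np.exp(-f))
                        g = (label - sig) * lr
                        for j in range(d):
                            grad[j] += g * syn1[target, j]
                            syn1[target, j] += g * h[j]
                    for j in range(d):
                        syn0[center, j] += grad[j]
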