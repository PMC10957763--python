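"""Independent brute-force oracles for the diffusion sampler.

These compute exact transition probabilities by direct enumeration from the
layer weight structure, sharing no code with the sampler they check.
"""

import numpy as np


def _layer_weight_dict(layer):
    w = {}
    for i in range(layer.n):
        for j, wt in zip(layer.neighbors[i], layer.weights[i]):
            w[(i, int(j))] = float(wt)
    return w


def _first_order(wdict, n, cur):
    out = {}
    tot = 0.0
    for (a, b), wt in wdict.items():
        if a == cur:
            out[b] = wt
            tot += wt
    return {b: v / tot for b, v in out.items()}


def _second_order(wdict, cur, prev, p, q):
    out = {}
    for (a, b), wt in wdict.items():
        if a != cur:
            continue
        if b == prev:
            out[b] = wt / p
        elif (prev, b) in wdict:
            out[b] = wt
        else:
            out[b] = wt / q
    tot = sum(out.values())
    return {b: v / tot for b, v in out.items()}


def exact_step_distributions(net, start, p, q):
    """Exact P(v1) and P(v1, v2) for a 2-step diffusion from ``start``.

    Layer choice at each step is informativeness-proportional; the
    second-order case applies in layer l iff the edge (v0, v1) exists in l.
    """
    ws = _layer_weight_dict(net.structural)
    wf = _layer_weight_dict(net.functional)
    layers = {"s": ws, "f": wf}

    def layer_probs(node):
        tot = net.info_s[node] + net.info_f[node]
        return {"s": net.info_s[node] / tot, "f": net.info_f[node] / tot}

    p1 = {}
    for tag, pl in layer_probs(start).items():
        for v1, pr in _first_order(layers[tag], net.n, start).items():
            p1[v1] = p1.get(v1, 0.0) + pl * pr

    p12 = {}
    for v1, pr1 in p1.items():
        for tag, pl in layer_probs(v1).items():
            w = layers[tag]
            if (start, v1) in w:
                dist = _second_order(w, v1, start, p, q)
            else:
                dist = _first_order(w, net.n, v1)
            for v2, pr2 in dist.items():
                p12[(v1, v2)] = p12.get((v1, v2), 0.0) + pr1 * pl * pr2
    return p1, p12


def empirical_two_step(net, start, n_walks, seed, p=0.1, q=1.6):
    """Sample n_walks two-step walks; return first- and two-step counts."""
    from brainwalk.diffusion import WalkConfig, _AliasCache, _walk

    config = WalkConfig(p=p, q=q, walk_length=2, walks_per_node=1, seed=seed)
    rng = np.random.default_rng(seed)
    cache = _AliasCache(net, p, q)
    first, second = {}, {}
    for _ in range(n_walks):
        w = _walk(net, start, config, rng, cache)
        first[w[1]] = first.get(w[1], 0) + 1
        second[(w[1], w[2])] = second.get((w[1], w[2]), 0) + 1
    return first, second


def chisquare_pvalue(counts, probs, n):
    """Goodness-of-fit p-value of observed counts against exact probabilities."""
    from scipy import stats

    keys = sorted(probs)
    observed = np.array([counts.get(k, 0) for k in keys], dtype=float)
    expected = np.array([probs[k] * n for k in keys])
    return stats.chisquare(observed, expected).pvalue


def node2vec_two_step(layer, start, p, q):
    """Exact P(v1, v2) of a plain second-order (p, q)-biased walk."""
    w = _layer_weight_dict(layer)
    p12 = {}
    for v1, pr1 in _first_order(w, layer.n, start).items():
        for v2, pr2 in _second_order(w, v1, start, p, q).items():
            p12[(v1, v2)] = p12.get((v1, v2), 0.0) + pr1 * pr2
    return p12
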