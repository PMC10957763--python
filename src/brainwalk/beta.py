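"""Beta-density refinement of connectivity strengths.

The mapping ``psi(x) = x * BetaPDF(x; alpha, beta)`` rescales connection
strengths in [0, 1]: in the monotone regime (alpha >= 1, beta = 1) it
squeezes weak connections toward zero and expands strong ones, with
``psi(1) = alpha``. A strength of 0.9 is only 80% larger than 0.5 raw, but
with alpha=2, beta=1 it maps to 1.62 versus 0.5 — a 224% increase — which
sharpens the contrast the diffusion sampler sees.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from brainwalk.io import ConnectivityMatrix


@dataclass(frozen=True)
class BetaParams:
    """Shape parameters of the beta density used by the mapping.

    Defaults alpha=10, beta=1: the monotone bounded configuration; for
    beta < 1 the density diverges as x -> 1, which would create unbounded
    refined weights, so only beta = 1 is used in practice.
    """

    alpha: float = 10.0
    beta: float = 1.0

    def __post_init__(self) -> None:
        if self.alpha <= 0 or self.beta <= 0:
            raise ValueError("alpha and beta must be positive")
        if self.alpha < 1 or self.beta > 1:
            warnings.warn(
                "beta mapping is monotone increasing only for alpha >= 1 and "
                f"beta <= 1; got alpha={self.alpha}, beta={self.beta}"
            )


def beta_map(x: float | np.ndarray, params: BetaParams) -> float | np.ndarray:
    """Evaluate ``psi(x) = x * BetaPDF(x; alpha, beta)`` for x in [0, 1].

    psi(0) = 0 always; for beta = 1 the map is monotone with maximum
    psi(1) = alpha.
    """
    arr = np.asarray(x, dtype=float)
    if (arr < 0).any() or (arr > 1).any():
        raise ValueError("beta mapping is defined on [0, 1]")
    out = arr * stats.beta.pdf(arr, params.alpha, params.beta)
    # the density is 0 outside support but pdf(0)=inf for alpha<1 etc.; the
    # multiplication by x=0 must yield exactly 0
    out = np.where(arr == 0.0, 0.0, out)
    if np.isscalar(x) or np.ndim(x) == 0:
        return float(out)
    return out


def refine_matrix(mat: ConnectivityMatrix, params: BetaParams) -> ConnectivityMatrix:
    """Apply the beta mapping elementwise to a connectivity matrix.

    Functional matrices are already in [0, 1]. Structural weights
    (fibers/area) are unbounded, so each subject's matrix is rescaled by its
    own maximum entry first; because the beta-1 map is a pure power map, a
    global rescale leaves all within-subject weight ratios (and hence walk
    transition probabilities) unchanged.
    """
    w = mat.weights
    if mat.modality == "structural":
        top = w.max()
        if top > 0:
            w = w / top
    if w.max() > 1.0 + 1e-12:
        raise ValueError("matrix entries exceed 1 after rescaling; cannot beta-map")
    mapped = beta_map(np.clip(w, 0.0, 1.0), params)
    return ConnectivityMatrix(mapped, mat.modality, list(mat.region_labels))
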