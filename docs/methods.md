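# Methods

This note documents the model, the choices that were genuinely open, the
numerical conventions, and what the synthetic experiments do and do not
demonstrate.

## Model and assumptions

The pipeline treats each subject's brain as a two-layer network over the
same `n` regions: a sparse structural layer (refined fiber-density weights)
and a functional layer pruned to a comparable scale. The working assumptions
are:

* Connection strength carries information multiplicatively: the beta-density
  refinement `ψ(x) = x·Beta(x; α, β)` with `β = 1` is the power map
  `α x^α`, so only *relative* weights matter downstream. A global rescaling
  of a subject's matrix (including the per-subject max-rescale applied to
  SC) changes no walk transition probability and no informativeness value.
  With `β < 1` the density diverges at `x → 1`, which would produce
  unbounded refined weights; `β` is therefore fixed to 1 and the package
  warns outside the monotone regime (`α ≥ 1`, `β ≤ 1`).
* A region that is strongly tied to only a few neighbors is more distinctive
  than a hub: informativeness `I_i = ln(e + |T_i|)` counts neighbors whose
  edge does not exceed the layer's mean weight (each undirected edge counted
  once in the mean, computed on refined weights since the layers are built
  from them).
* Walk contexts identify node roles: the skip-gram objective with negative
  sampling assumes conditional independence of context predictions and
  symmetric input/output roles; the input vectors are the representation.

## Tunable parameters

| parameter | default | meaning |
|---|---|---|
| α, β | 10, 1 | beta-mapping shape; α is the refined weight of a maximal connection |
| θ | 0.5 | functional layer scale relative to structural mean degree |
| p, q | 0.1, 1.6 | return and in-out bias of the second-order walk (localized diffusion) |
| λ (walk_length) | 10 | steps per walk; a walk holds λ+1 node ids |
| r (walks_per_node) | 10 | walks started per node per network |
| d | 80 | embedding dimension |
| window, negatives, epochs, lr | 10, 5, 5, 0.025 | skip-gram training conventions of this model family |
| k | d/2 | retained principal components, capped at min(n−1, d−1) |
| folds × repeats | 10 × 10 | stratified cross-validation protocol |

All defaults are recorded in every run's `config.yaml`. `walks_per_node`,
the skip-gram optimizer settings, and the SVM (linear kernel, C = 1, on
standardized features) are conventions, not derived quantities; they are
logged so runs are auditable.

`k` deserves a caveat: for an `n`-region subject only `n − 1` principal
components exist, so the `d/2` default is capped (a 30-region cohort gets
k = 29). The low-variance tail mostly carries sampling noise; it is retained
because the variance-ordered truncation at `d/2` is part of the method's
definition, and cosine distances weight columns by their score magnitude, so
the tail's influence is bounded.

## Cross-subject comparability of representations

Embeddings are trained per subject, so their coordinate frames are only
comparable up to the stabilizing effect of per-subject PCA. Two conventions
make the PCA scores line up across subjects:

* **Sign.** Each score column is flipped so that its projection onto a
  frozen pseudorandom reference sequence over node ids (seed 12345, the same
  for every subject) is positive. A convention based on the loading vector
  cannot work here: loadings live in the subject-specific embedding basis,
  which is arbitrary up to rotation, whereas score columns are indexed by
  the shared nodes.
* **Order.** Components are ordered by explained variance. This is only
  identifiable when the leading eigenvalues are separated; cohorts whose
  community structure is too symmetric produce near-degenerate spectra and
  the order can swap between subjects. The synthetic generator deliberately
  uses communities of unequal size and graded cohesion to stay in the
  identifiable regime (real connectomes are heterogeneous in exactly this
  way). No orthogonal (Procrustes) alignment across subjects is performed;
  the residual rotation ambiguity within nearly-tied components is a known
  limitation.

## Templates, jackknifing, and leakage control

Group templates are centroids — per-node rows `τ_i` for region-level
distances, concatenated `n·k` vectors `C±` for network-level distances. Two
self-reference corrections matter:

* **Node statistics.** A subject included in a centroid is biased toward it
  (its distance shrinks by roughly one part in the group size, and the
  bias is amplified when between-subject correlations are weak). Subjects
  belonging to the template's group are therefore compared against the
  jackknifed centroid that excludes them.
* **Classification.** Network templates are rebuilt inside every training
  fold, and each *training* subject's own-group template is likewise
  jackknifed: without this, training rows carry a member bias that test
  rows cannot have, and under the null the SVM systematically inverts
  (measured ACC ≈ 0.31 at zero effect before the correction; chance after).
  Test subjects always use the full training-fold templates, so no test
  information reaches the features.

Region screening runs the two-sample test (Welch by default, pooled Student
available) against *both* group templates and takes the union of flagged
regions, splitting the Bonferroni budget across the two families
(`0.05/(2n)` per test) so the union still controls the family-wise error
rate.

## Numerical conventions

* Cosine distance `1 − cos` is clipped to `[0, 2]`; a zero vector inside a
  cohort loop records the maximum distance 2 with a warning instead of
  aborting (strict errors at the single-pair API).
* Matrices are symmetrized by averaging when asymmetry is ≤ 1e-8 and
  rejected beyond that; diagonals are forced to zero; negative and
  self-correlations are zeroed before refinement. A constant time series
  yields zero correlations with a warning.
* Functional top-k nomination uses round-half-up of `θ·avg_s` with a floor
  of one, ties broken by ascending node index; the edge set is the union of
  nominations (the per-node top-k is inherently directed, the layer is
  undirected).
* Walks: the layer is re-chosen at every step including the first; the
  second-order case applies exactly when the edge (previous, current)
  exists in the chosen layer; a node isolated in the chosen layer forces a
  switch, and isolation in both layers ends the walk. Alias tables give
  O(1) draws (two uniforms each); tables are built once per (layer, node)
  and per (layer, previous, current) as needed.
* Skip-gram training is single-threaded with an internal xorshift RNG, so
  results are bit-reproducible for a given seed. The noise distribution is
  the corpus unigram frequency to the 3/4 power.

## Synthetic cohorts: what they emulate and what they do not

`brainwalk.synthetic` generates cohorts of 30-region subjects (20 per arm
by default): a shared modular SC backbone (density 0.25, within:between
edge-probability ratio 6:1, lognormal weights, graded community cohesion),
per-subject lognormal weight jitter (σ = 0.3), and FC computed from T = 200
simulated timepoints in which each region follows its community's latent
signal plus an SC-weighted mix of its neighbors' signals plus unit
observation noise.

The group effect is a *dysconnectivity*: each designated affected region in
patients shifts its latent coupling toward a foreign community — FC signal
`(z_own + δ·z_target)/√(1+δ²)`, SC edges toward the target community scaled
by `(1+δ)` and within the home community by `1/(1+δ)`. A pure uniform
scaling of a region's couplings would be invisible to this method by
construction (normalized transitions, cosine distances), so the injected
effect must change the connectivity *pattern*; altered inter-community
coupling is also the phenotype reported for the disorders this emulates.
At δ = 0 the patient and control generators are identical.

What passing tests show: the full pipeline recovers pattern-changing,
regionally localized effects of the injected magnitude, stays at chance on
null cohorts, and controls the family-wise error rate. What they do not
show: performance on real imaging data — the generator has no hemodynamics,
no measurement artifacts, no demographic confounds, and its community
structure is cleaner than a real parcellation's.

## Problem sizes used in the calibration suites

Large replication counts (200 null cohorts for error-rate calibration, 20
null runs for the zero-discovery check) use a reduced preset:
5 walks/node of length 8, d = 24, window 5, 3 epochs, k = 12
(~0.6 s per cohort). The preset is intentionally kept above a degeneracy
threshold: with far less sampling the embeddings retain no cross-subject
structure, templates collapse toward zero vectors, and template-referenced
cosine distances become ill-conditioned (this regime is detectable as
near-zero pairwise node-row correlations between subjects). Recovery and
classification checks run at the full default sizes on 30-region,
20+20-subject cohorts.

## Known limitations

* Only two layers (structural + functional) and pairwise two-group
  analyses; no multi-class protocol.
* No cross-subject Procrustes alignment; comparability rests on per-subject
  PCA with the conventions above and degrades when leading eigenvalues tie.
* Bonferroni is the only multiplicity correction offered.
* The skip-gram trainer is single-threaded by design for reproducibility;
  cohorts embarrassingly parallelize at the subject level outside the
  library if needed.
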