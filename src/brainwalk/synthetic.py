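"""Synthetic multimodal cohorts with localized, controllable group effects.

Each cohort shares a modular structural backbone (stochastic-block style:
dense within communities, sparse between), because the diffusion/embedding
stack is only meaningful on networks with mesoscale structure. Per subject:

* SC — the backbone weights jittered by lognormal subject noise;
* FC — Pearson correlations of simulated regional time series, where region
  i follows its community's latent signal plus a structural mix of its
  neighbors' community signals plus independent observation noise.

For subjects in a patient group the effect is a *dysconnectivity* of the
configured ``affected_regions``: each affected region shifts part of its
latent coupling away from its own community toward a designated foreign
community, with the shift magnitude set by delta. In FC the region's latent
signal becomes (z_own + delta * z_target) / sqrt(1 + delta^2) before
observation noise; in SC the region's edges toward the target community are
scaled by (1 + delta) and those within its own community by 1/(1 + delta).
The perturbation changes the *pattern* (direction) of the region's
connectivity profile, not just its overall strength — a pure row scaling
would be invisible to normalized walk transitions and cosine distances.
Both modalities are perturbed by default (SC-only or FC-only effects are
available to probe cross-modal complementarity). delta = 0 makes patient
and control generators identical in distribution.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from brainwalk.io import (
    ConnectivityMatrix,
    SubjectRecord,
    TimeSeriesMatrix,
    fc_from_timeseries,
    write_connectivity_matrix,
)


@dataclass
class SyntheticConfig:
    """Cohort-level generation parameters.

    Defaults describe the study condition used throughout the test suite:
    30 regions in 3 equal communities, 20 subjects per arm, 5 affected
    regions spread over the communities, effect size delta = 2, unit
    observation noise, T = 200 timepoints (a short resting-state-like run).
    """

    n_regions: int = 30
    n_per_group: dict[str, int] = field(default_factory=lambda: {"ctrl": 20, "pat": 20})
    n_communities: int = 3
    sc_density: float = 0.25
    affected_regions: tuple[int, ...] = (3, 8, 14, 21, 27)
    effect_size: float = 2.0
    noise_sd: float = 1.0
    t_len: int = 200
    seed: int = 0
    patient_groups: tuple[str, ...] = ("pat",)
    effect_modality: str = "both"  # both | sc | fc
    subject_sc_sigma: float = 0.3
    mix_strength: float = 0.5
    within_between_ratio: float = 6.0

    def __post_init__(self) -> None:
        if not 0 < self.sc_density <= 1:
            raise ValueError("sc_density must be in (0, 1]")
        if self.effect_size < 0:
            raise ValueError("effect_size must be >= 0")
        if any(not 0 <= r < self.n_regions for r in self.affected_regions):
            raise ValueError("affected_regions out of range")
        if self.effect_modality not in ("both", "sc", "fc"):
            raise ValueError("effect_modality must be both, sc or fc")
        if self.t_len < 3:
            raise ValueError("need at least 3 timepoints")

    @property
    def communities(self) -> np.ndarray:
        """Block assignment: contiguous communities of unequal size.

        Sizes follow descending proportions (K+1-c weighting). Equal-size
        blocks would make the leading eigenvalues of the connectivity
        structure nearly degenerate, an artificial symmetry real connectomes
        do not have (and one that makes any variance-ordered representation
        unidentifiable across subjects).
        """
        k = self.n_communities
        weights = np.arange(k, 0, -1) + 1.0
        sizes = np.floor(weights / weights.sum() * self.n_regions).astype(int)
        sizes[: self.n_regions - sizes.sum()] += 1
        return np.repeat(np.arange(k), sizes)


def _base_backbone(config: SyntheticConfig) -> np.ndarray:
    """Cohort-shared weighted modular SC backbone (depends on seed only)."""
    rng = np.random.default_rng([config.seed, 0xB5])
    n = config.n_regions
    comm = config.communities
    same = comm[:, None] == comm[None, :]
    # solve for within/between edge probabilities hitting the target density
    frac_within = (same.sum() - n) / (n * (n - 1))
    ratio = config.within_between_ratio
    p_between = config.sc_density / (frac_within * ratio + (1 - frac_within))
    p_within = min(1.0, ratio * p_between)
    prob = np.where(same, p_within, p_between)
    iu = np.triu_indices(n, k=1)
    present = rng.random(len(iu[0])) < prob[iu]
    weights = np.exp(rng.normal(0.0, 0.5, size=len(iu[0])))
    # graded within-module coupling strength: communities differ in internal
    # cohesion, which keeps the leading spectral components well separated
    cohesion = 1.5 ** np.arange(config.n_communities, 0, -1)
    scale = np.where(same, cohesion[comm][:, None], 1.0)
    base = np.zeros((n, n))
    base[iu] = np.where(present, weights * scale[iu], 0.0)
    return base + base.T


def _affected_mask(config: SyntheticConfig) -> np.ndarray:
    mask = np.zeros(config.n_regions, dtype=bool)
    mask[list(config.affected_regions)] = True
    return mask


def generate_subject(
    config: SyntheticConfig,
    group: str,
    rng: np.random.Generator,
    base: np.ndarray | None = None,
) -> tuple[ConnectivityMatrix, ConnectivityMatrix]:
    """Draw one subject's (structural, functional) connectivity pair."""
    if base is None:
        base = _base_backbone(config)
    n = config.n_regions
    comm = config.communities
    affected = _affected_mask(config)
    is_patient = group in config.patient_groups
    delta = config.effect_size if is_patient else 0.0
    # each affected region couples toward the next community over
    target = (comm + 1) % config.n_communities

    # --- structural: jittered backbone; affected rows rebalanced toward the
    # target community (pattern change, total strength roughly preserved)
    jitter = np.exp(rng.normal(0.0, config.subject_sc_sigma, size=(n, n)))
    jitter = np.triu(jitter, k=1)
    jitter = jitter + jitter.T
    sc = base * jitter
    if delta > 0 and config.effect_modality in ("both", "sc"):
        scale = np.ones((n, n))
        for i in np.flatnonzero(affected):
            toward = comm == target[i]
            within = comm == comm[i]
            scale[i, toward] *= 1.0 + delta
            scale[toward, i] *= 1.0 + delta
            scale[i, within] /= 1.0 + delta
            scale[within, i] /= 1.0 + delta
        sc = sc * scale
    sc_mat = ConnectivityMatrix(sc, "structural")

    # --- functional: latent community signals mixed through the SC backbone
    z = rng.standard_normal((config.n_communities, config.t_len))
    own = z[comm].copy()
    if delta > 0 and config.effect_modality in ("both", "fc"):
        idx = np.flatnonzero(affected)
        own[idx] = (z[comm[idx]] + delta * z[target[idx]]) / np.sqrt(1.0 + delta**2)
    row_sum = sc.sum(axis=1, keepdims=True)
    mix_w = np.divide(sc, row_sum, out=np.zeros_like(sc), where=row_sum > 0)
    mixed = mix_w @ z[comm]
    x = own + config.mix_strength * mixed
    x = x + config.noise_sd * rng.standard_normal((n, config.t_len))
    fc_mat = fc_from_timeseries(TimeSeriesMatrix(x))
    return sc_mat, fc_mat


def generate_cohort_arrays(
    config: SyntheticConfig,
) -> tuple[list[ConnectivityMatrix], list[ConnectivityMatrix], list[str], list[str]]:
    """In-memory cohort: (sc_list, fc_list, group_labels, subject_ids)."""
    base = _base_backbone(config)
    sc_list, fc_list, labels, ids = [], [], [], []
    for group, count in config.n_per_group.items():
        for j in range(count):
            rng = np.random.default_rng([config.seed, zlib.crc32(group.encode()), j])
            sc, fc = generate_subject(config, group, rng, base=base)
            sc_list.append(sc)
            fc_list.append(fc)
            labels.append(group)
            ids.append(f"{group}{j:03d}")
    return sc_list, fc_list, labels, ids


def generate_cohort(config: SyntheticConfig, out_dir: str | Path) -> Path:
    """Write per-subject SC/FC TSVs plus a manifest; returns the manifest path."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sc_list, fc_list, labels, ids = generate_cohort_arrays(config)
    rows = []
    for sid, group, sc, fc in zip(ids, labels, sc_list, fc_list):
        sc_name = f"{sid}_sc.tsv"
        fc_name = f"{sid}_fc.tsv"
        write_connectivity_matrix(sc, out_dir / sc_name)
        write_connectivity_matrix(fc, out_dir / fc_name)
        rows.append((sid, group, sc_name, fc_name))
    manifest = out_dir / "manifest.tsv"
    with open(manifest, "w") as fh:
        fh.write("subject_id\tgroup\tsc_path\tfc_path\n")
        for row in rows:
            fh.write("\t".join(row) + "\n")
    return manifest


def records_to_arrays(
    records: list[SubjectRecord],
) -> tuple[list[ConnectivityMatrix], list[ConnectivityMatrix], list[str], list[str]]:
    """Load a manifest's subjects into memory (helper for the pipeline)."""
    from brainwalk.io import read_connectivity_matrix

    sc_list = [read_connectivity_matrix(r.sc_source, "structural") for r in records]
    fc_list = [read_connectivity_matrix(r.fc_source, "functional") for r in records]
    return sc_list, fc_list, [r.group_label for r in records], [r.subject_id for r in records]
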