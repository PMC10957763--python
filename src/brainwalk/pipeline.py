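"""End-to-end cohort analysis: refine -> multilayer -> walk -> embed -> PCA
-> templates/distances -> statistics + classification.

`analyze_cohort` is the in-memory engine; `run_pipeline` wraps it with disk
I/O (manifest in, TSV artifacts and a resolved-config record out). Per-stage
seeds are derived deterministically from the master seed and subject index,
so a run is reproducible end to end in single-worker mode.
"""

from __future__ import annotations

import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from brainwalk.beta import BetaParams, refine_matrix
from brainwalk.diffusion import WalkConfig, generate_corpus
from brainwalk.distances import (
    ReconfiguredMatrix,
    _safe_row_distance,
    build_network_templates,
    build_node_template,
    concatenate_network,
    network_distance_matrix,
    node_distance_matrix,
    pca_reconfigure,
)
from brainwalk.embedding import train_embeddings
from brainwalk.evaluation import (
    ClassificationReport,
    NodeStatsReport,
    cross_validated_classify,
    nodewise_ttests,
)
from brainwalk.io import ConnectivityMatrix, read_cohort_manifest
from brainwalk.multilayer import build_multilayer

logger = logging.getLogger(__name__)


@dataclass
class PipelineParams:
    """All tunables of the analysis, with the method's default settings.

    alpha=10, beta=1 (beta mapping); theta=0.5 (functional layer at half the
    structural network scale); p=0.1, q=1.6, walk_length=10 (localized
    diffusion); dim=80, k=dim/2 (embedding and retained components). The
    remaining knobs (walks_per_node, window, negatives, epochs, SVM settings)
    are the standard conventions of this model family.
    """

    alpha: float = 10.0
    beta: float = 1.0
    theta: float = 0.5
    p: float = 0.1
    q: float = 1.6
    walk_length: int = 10
    walks_per_node: int = 10
    dim: int = 80
    window: int = 10
    negatives: int = 5
    epochs: int = 5
    k: int | None = None  # None -> dim // 2, capped by available components
    folds: int = 10
    repeats: int = 10
    test: str = "welch"
    svm_c: float = 1.0

    def resolved_k(self, n_regions: int) -> int:
        k = self.k if self.k is not None else self.dim // 2
        return min(k, n_regions - 1, self.dim - 1)

    @classmethod
    def small(cls) -> "PipelineParams":
        """Reduced problem sizes for large calibration sweeps.

        Deliberately kept above the degeneracy threshold: with too few
        walks/epochs the representations lose all cross-subject structure,
        group templates collapse toward zero vectors, and cosine distances
        to them become ill-conditioned.
        """
        return cls(
            walks_per_node=5, walk_length=8, dim=24, window=5, epochs=3, k=12
        )


@dataclass
class CohortResult:
    """Everything `analyze_cohort` computes for one cohort.

    ``stats_reports`` holds one t-test report per reference template (the
    negative and the positive group's); a region counts as significant if it
    is flagged against either template, with the Bonferroni budget split
    across the two families. ``L`` is the node-distance matrix against the
    negative (reference) template.
    """

    A: list[ReconfiguredMatrix]
    labels: list[str]
    L: np.ndarray
    stats_reports: dict[str, NodeStatsReport]
    classification: ClassificationReport | None
    params: PipelineParams
    seed: int

    @property
    def stats(self) -> NodeStatsReport:
        """Report against the negative-group template (for convenience)."""
        return next(iter(self.stats_reports.values()))

    def significant_regions(self) -> list[int]:
        """Union of Bonferroni-significant regions over both templates."""
        out: set[int] = set()
        for rep in self.stats_reports.values():
            out |= set(rep.significant_regions())
        return sorted(out)


def embed_subject(
    sc: ConnectivityMatrix,
    fc: ConnectivityMatrix,
    params: PipelineParams,
    seed: int,
) -> ReconfiguredMatrix:
    """One subject: beta-refine both matrices, build the multilayer network,
    sample the walk corpus, train embeddings, and PCA-reconfigure them."""
    bp = BetaParams(params.alpha, params.beta)
    bw_s = refine_matrix(sc, bp)
    bw_f = refine_matrix(fc, bp)
    net = build_multilayer(bw_s, bw_f, theta=params.theta)
    corpus = generate_corpus(
        net,
        WalkConfig(
            p=params.p,
            q=params.q,
            walk_length=params.walk_length,
            walks_per_node=params.walks_per_node,
            seed=seed,
        ),
    )
    emb = train_embeddings(
        corpus,
        d=params.dim,
        window=params.window,
        negatives=params.negatives,
        epochs=params.epochs,
        seed=seed,
    )
    return pca_reconfigure(emb, params.resolved_k(sc.n_regions))


def _subject_seed(master_seed: int, index: int) -> int:
    return int(np.random.SeedSequence([master_seed, index]).generate_state(1)[0] % 2**31)


def analyze_cohort(
    sc_list: list[ConnectivityMatrix],
    fc_list: list[ConnectivityMatrix],
    labels: list[str],
    positive_label: str,
    negative_label: str,
    params: PipelineParams | None = None,
    seed: int = 0,
    classify: bool = True,
) -> CohortResult:
    """Run the full analysis for a two-group cohort.

    Node statistics compare the two groups' distances to the negative
    (reference) group's template, jackknifed for its own members.
    Classification uses leak-free per-fold network templates.
    """
    params = params or PipelineParams()
    if len(sc_list) != len(fc_list) or len(sc_list) != len(labels):
        raise ValueError("sc_list, fc_list and labels must have equal length")
    labels_arr = np.asarray(labels)

    A = [
        embed_subject(sc, fc, params, _subject_seed(seed, i))
        for i, (sc, fc) in enumerate(zip(sc_list, fc_list))
    ]

    # --- region-level statistics against each group's template; the 0.05
    # Bonferroni budget is split over the two test families so the union of
    # flagged regions still controls the family-wise error rate
    stats_reports: dict[str, NodeStatsReport] = {}
    L_by_template: dict[str, np.ndarray] = {}
    for ref_label in (negative_label, positive_label):
        ref_idx = np.flatnonzero(labels_arr == ref_label)
        template = build_node_template([A[i] for i in ref_idx], ref_label)
        L_ref = node_distance_matrix(A, template, member_indices=ref_idx.tolist())
        L_by_template[ref_label] = L_ref
        stats_reports[ref_label] = nodewise_ttests(
            L_ref,
            labels,
            positive_label,
            negative_label,
            test=params.test,
            alpha=0.05 / 2,
            template_label=ref_label,
        )
    L = L_by_template[negative_label]

    classification = None
    if classify:
        classification = cross_validated_classify(
            network_h_builder(A, labels_arr, positive_label, negative_label),
            labels,
            positive_label,
            folds=params.folds,
            repeats=params.repeats,
            seed=seed,
            C=params.svm_c,
        )

    return CohortResult(A, list(labels), L, stats_reports, classification, params, seed)


def network_h_builder(
    A: list[ReconfiguredMatrix],
    labels: np.ndarray,
    positive_label: str,
    negative_label: str,
):
    """Per-fold network-distance features with jackknifed training rows.

    Templates C+/C- are group means over training-fold subjects only. A
    training subject sitting inside its own group's centroid is biased
    toward it, while a test subject belongs to neither template; without a
    correction the classifier learns that bias and systematically inverts on
    test folds under the null. Each training subject is therefore compared
    against its own-group template recomputed without it; test subjects use
    the full training templates.
    """
    labels = np.asarray(labels)
    conc = np.stack([concatenate_network(a) for a in A])

    def h_builder(train_idx: np.ndarray, test_idx: np.ndarray):
        pos_idx = [i for i in train_idx if labels[i] == positive_label]
        neg_idx = [i for i in train_idx if labels[i] == negative_label]
        if len(pos_idx) < 2 or len(neg_idx) < 2:
            raise ValueError("each training fold needs >= 2 subjects per group")
        c_plus = conc[pos_idx].mean(axis=0)
        c_minus = conc[neg_idx].mean(axis=0)
        m_pos, m_neg = len(pos_idx), len(neg_idx)
        H_train = np.empty((len(train_idx), 2))
        for r, i in enumerate(train_idx):
            cp, cm = c_plus, c_minus
            if labels[i] == positive_label:
                cp = (m_pos * c_plus - conc[i]) / (m_pos - 1)
            elif labels[i] == negative_label:
                cm = (m_neg * c_minus - conc[i]) / (m_neg - 1)
            H_train[r, 0] = _safe_row_distance(conc[i], cp)
            H_train[r, 1] = _safe_row_distance(conc[i], cm)
        H_test = np.empty((len(test_idx), 2))
        for r, i in enumerate(test_idx):
            H_test[r, 0] = _safe_row_distance(conc[i], c_plus)
            H_test[r, 1] = _safe_row_distance(conc[i], c_minus)
        return H_train, H_test

    return h_builder


def cohort_network_distances(
    A: list[ReconfiguredMatrix], labels: list[str], positive_label: str, negative_label: str
) -> np.ndarray:
    """Whole-cohort H (both templates from all subjects; for inspection, not
    for leak-free classification)."""
    labels_arr = np.asarray(labels)
    pos = [a for a, l in zip(A, labels_arr) if l == positive_label]
    neg = [a for a, l in zip(A, labels_arr) if l == negative_label]
    c_plus, c_minus = build_network_templates(pos, neg)
    return network_distance_matrix(A, c_plus, c_minus)


def _write_matrix(path: Path, mat: np.ndarray, row_labels: list[str]) -> None:
    with open(path, "w") as fh:
        for lab, row in zip(row_labels, mat):
            fh.write(lab + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def run_pipeline(
    manifest: str | Path,
    out_dir: str | Path,
    positive_label: str,
    negative_label: str,
    params: PipelineParams | None = None,
    seed: int = 0,
) -> CohortResult:
    """Disk-facing pipeline: read a cohort manifest, analyze, persist artifacts.

    Writes per-subject reconfigured matrices, the node-distance matrix L,
    the whole-cohort network-distance matrix H, the statistics and
    classification reports, and the resolved configuration.
    """
    params = params or PipelineParams()
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    records = read_cohort_manifest(manifest)
    from brainwalk.synthetic import records_to_arrays

    sc_list, fc_list, labels, ids = records_to_arrays(records)
    wanted = [i for i, l in enumerate(labels) if l in (positive_label, negative_label)]
    sc_list = [sc_list[i] for i in wanted]
    fc_list = [fc_list[i] for i in wanted]
    labels = [labels[i] for i in wanted]
    ids = [ids[i] for i in wanted]
    shapes = {sc.n_regions for sc in sc_list} | {fc.n_regions for fc in fc_list}
    if len(shapes) != 1:
        raise ValueError(f"subjects disagree on region count: {sorted(shapes)}")

    result = analyze_cohort(
        sc_list, fc_list, labels, positive_label, negative_label, params=params, seed=seed
    )

    for sid, a in zip(ids, result.A):
        _write_matrix(out_dir / f"{sid}_A.tsv", a.A, [f"ROI{i}" for i in range(a.n)])
    _write_matrix(out_dir / "L.tsv", result.L, ids)
    H = cohort_network_distances(result.A, labels, positive_label, negative_label)
    _write_matrix(out_dir / "H.tsv", H, ids)
    for ref_label, rep in result.stats_reports.items():
        rep.write(out_dir / f"node_stats_vs_{ref_label}.tsv", sc_list[0].region_labels)
    if result.classification is not None:
        result.classification.write(out_dir / "classification.txt")
    resolved = asdict(params)
    resolved.update(
        seed=seed,
        positive_label=positive_label,
        negative_label=negative_label,
        n_subjects=len(ids),
        n_regions=sc_list[0].n_regions,
        k_resolved=params.resolved_k(sc_list[0].n_regions),
    )
    with open(out_dir / "config.yaml", "w") as fh:
        yaml.safe_dump(resolved, fh)
    logger.info("pipeline run complete: %s", out_dir)
    return result
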