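"""Region-level statistics and network-level classification.

Regions are screened with two-sample two-tailed t-tests on each column of
the node-distance matrix, Bonferroni-corrected at 0.05/n. Subjects are
classified from their two network-distance features with a linear SVM under
repeated stratified cross-validation; both templates and distance features
are recomputed from training-fold subjects only, so no test subject leaks
into its own reference coordinates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
from scipy import stats
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


@dataclass
class NodeStatsReport:
    """Per-region t statistics with Bonferroni-corrected significance."""

    t: np.ndarray
    p: np.ndarray
    significant: np.ndarray
    group_a: str
    group_b: str
    template_label: str
    alpha: float = 0.05

    @property
    def corrected_threshold(self) -> float:
        return self.alpha / len(self.p)

    def significant_regions(self) -> list[int]:
        return np.flatnonzero(self.significant).tolist()

    def write(self, path, region_labels: Sequence[str] | None = None) -> None:
        labels = region_labels or [f"ROI{i}" for i in range(len(self.p))]
        with open(path, "w") as fh:
            fh.write("region\tt\tp\tsignificant\n")
            for lab, t, p, s in zip(labels, self.t, self.p, self.significant):
                fh.write(f"{lab}\t{t!r}\t{p!r}\t{int(s)}\n")


@dataclass
class FoldResult:
    repeat: int
    fold: int
    tp: int
    tn: int
    fp: int
    fn: int


@dataclass
class ClassificationReport:
    """Cross-validated ACC/SEN/SPE/AUC with per-fold confusion counts."""

    acc: float
    sen: float
    spe: float
    auc: float
    folds: list[FoldResult] = field(default_factory=list)
    seed: int | None = None

    def write(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(
                f"ACC\t{self.acc!r}\nSEN\t{self.sen!r}\nSPE\t{self.spe!r}\n"
                f"AUC\t{self.auc!r}\nseed\t{self.seed}\n"
            )


def nodewise_ttests(
    L: np.ndarray,
    labels: Sequence[str],
    group_a: str,
    group_b: str,
    test: str = "welch",
    alpha: float = 0.05,
    template_label: str = "",
) -> NodeStatsReport:
    """Two-sample two-tailed t-test per region column of L, Bonferroni 0.05/n.

    ``test`` selects Welch (default) or pooled-variance Student. A region
    with zero variance in both groups has no defined statistic; its p is
    recorded as 1 with a warning.
    """
    labels = np.asarray(labels)
    a = L[labels == group_a]
    b = L[labels == group_b]
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs at least 2 subjects")
    if test not in ("welch", "student"):
        raise ValueError(f"unknown test variant {test!r}")
    n = L.shape[1]
    tvals = np.zeros(n)
    pvals = np.ones(n)
    for i in range(n):
        if a[:, i].std() == 0 and b[:, i].std() == 0:
            warnings.warn(f"region {i}: zero variance in both groups; p set to 1")
            continue
        t, p = stats.ttest_ind(a[:, i], b[:, i], equal_var=(test == "student"))
        tvals[i], pvals[i] = t, p
    return NodeStatsReport(
        t=tvals,
        p=pvals,
        significant=pvals < alpha / n,
        group_a=group_a,
        group_b=group_b,
        template_label=template_label,
        alpha=alpha,
    )


def classification_metrics(tp: int, tn: int, fp: int, fn: int) -> tuple[float, float, float]:
    """ACC=(TP+TN)/(TP+FN+TN+FP), SEN=TP/(TP+FN), SPE=TN/(TN+FP).

    A zero denominator yields NaN with a warning rather than an error.
    """
    if min(tp, tn, fp, fn) < 0:
        raise ValueError("confusion counts must be nonnegative")

    def ratio(num: float, den: float, name: str) -> float:
        if den == 0:
            warnings.warn(f"{name} undefined (zero denominator)")
            return math.nan
        return num / den

    acc = ratio(tp + tn, tp + fn + tn + fp, "ACC")
    sen = ratio(tp, tp + fn, "SEN")
    spe = ratio(tn, tn + fp, "SPE")
    return acc, sen, spe


def cross_validated_classify(
    h_builder: Callable[[np.ndarray, np.ndarray], tuple[np.ndarray, np.ndarray]],
    labels: Sequence[str],
    positive_label: str,
    folds: int = 10,
    repeats: int = 10,
    seed: int = 0,
    C: float = 1.0,
) -> ClassificationReport:
    """Repeated stratified k-fold SVM classification on network distances.

    ``h_builder(train_idx, test_idx)`` must return (H_train, H_test), the
    two-column distance features computed against templates built from the
    training subjects only. ACC/SEN/SPE are derived from confusion counts
    pooled per repeat and averaged over repeats; AUC is computed per repeat
    from the pooled signed decision function and averaged.
    """
    labels = np.asarray(labels)
    y = (labels == positive_label).astype(int)
    counts = np.bincount(y)
    if counts.min() < folds:
        raise ValueError(
            f"smallest class has {counts.min()} subjects; cannot stratify into {folds} folds"
        )
    accs, sens, spes, aucs = [], [], [], []
    fold_results: list[FoldResult] = []
    for rep in range(repeats):
        skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        tp = tn = fp = fn = 0
        scores = np.empty(len(y))
        for fold_i, (train_idx, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
            H_train, H_test = h_builder(train_idx, test_idx)
            # distances live on an arbitrary numeric scale; standardize on the
            # training fold so the margin penalty C is meaningful
            clf = make_pipeline(StandardScaler(), SVC(kernel="linear", C=C))
            clf.fit(H_train, y[train_idx])
            pred = clf.predict(H_test)
            dec = clf.decision_function(H_test)
            scores[test_idx] = dec
            yt = y[test_idx]
            ftp = int(np.sum((pred == 1) & (yt == 1)))
            ftn = int(np.sum((pred == 0) & (yt == 0)))
            ffp = int(np.sum((pred == 1) & (yt == 0)))
            ffn = int(np.sum((pred == 0) & (yt == 1)))
            tp, tn, fp, fn = tp + ftp, tn + ftn, fp + ffp, fn + ffn
            fold_results.append(FoldResult(rep, fold_i, ftp, ftn, ffp, ffn))
        acc, sen, spe = classification_metrics(tp, tn, fp, fn)
        accs.append(acc)
        sens.append(sen)
        spes.append(spe)
        aucs.append(roc_auc_score(y, scores))
    return ClassificationReport(
        acc=float(np.mean(accs)),
        sen=float(np.mean(sens)),
        spe=float(np.mean(spes)),
        auc=float(np.mean(aucs)),
        folds=fold_results,
        seed=seed,
    )
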