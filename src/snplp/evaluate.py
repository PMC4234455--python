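"""Evaluation protocols for SNP rankings.

Three procedures: (1) stratified five-fold cross-validated kNN AUC over
panels of top-ranked SNPs, with the ranking recomputed on the training
folds only (and a cross-dataset variant where the panel comes from a
second cohort); (2) top-n reproducibility between two rankings; and (3)
precision-recall / ROC retrieval of known causal SNPs from a synthetic
dataset.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.model_selection import StratifiedKFold

from .dataset import CASE, CONTROL, MISSING, GenotypeDataset
from .ranking import RankedList
from .simulate import SyntheticTruth

DEFAULT_PANEL_SIZES = (1, 2, 5, 10, 50, 100, 500, 1000)
DEFAULT_K_NEIGHBORS = 11  # odd, avoids vote ties; not prescribed by the protocol


@dataclass
class EvaluationReport:
    """Results of one evaluation run."""

    method: str
    panel_sizes: list[int]
    auc_by_n: dict[int, tuple[float, float, float] | None]  # n -> (AUC, lo, hi)
    k_neighbors: int
    n_folds: int
    seed: int
    fold_assignments: np.ndarray | None = None
    reproducibility_by_depth: dict[int, float] = field(default_factory=dict)
    pr_points: list[tuple[float, float]] = field(default_factory=list)
    roc_points: list[tuple[float, float]] = field(default_factory=list)
    pr_auc: float | None = None
    roc_auc: float | None = None

    def to_dict(self) -> dict:
        return {
            "method": self.method,
            "panel_sizes": list(self.panel_sizes),
            "auc_by_n": {
                str(n): (None if v is None else
                         {"auc": v[0], "ci_lower": v[1], "ci_upper": v[2]})
                for n, v in self.auc_by_n.items()
            },
            "k_neighbors": self.k_neighbors,
            "n_folds": self.n_folds,
            "seed": self.seed,
            "reproducibility_by_depth": dict(self.reproducibility_by_depth),
            "pr_auc": self.pr_auc,
            "roc_auc": self.roc_auc,
        }


# ---------------------------------------------------------------------------
# AUC primitives
# ---------------------------------------------------------------------------

def mann_whitney_auc(scores: np.ndarray, labels: np.ndarray) -> float:
    """AUC by the Mann-Whitney rank-sum formulation with midrank ties.

    ``labels`` are 1 for cases, 0 for controls.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(bool)
    n_pos, n_neg = int(labels.sum()), int((~labels).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC requires both classes")
    ranks = rankdata(scores, method="average")
    return float((ranks[labels].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg))


def hanley_mcneil_ci(auc: float, n_pos: int, n_neg: int, level: float = 0.95):
    """Hanley-McNeil standard-error confidence interval for an AUC."""
    q1 = auc / (2.0 - auc)
    q2 = 2.0 * auc**2 / (1.0 + auc)
    var = (
        auc * (1.0 - auc)
        + (n_pos - 1) * (q1 - auc**2)
        + (n_neg - 1) * (q2 - auc**2)
    ) / (n_pos * n_neg)
    se = float(np.sqrt(max(var, 0.0)))
    z = float(norm.ppf(0.5 + level / 2.0))
    return max(0.0, auc - z * se), min(1.0, auc + z * se)


# ---------------------------------------------------------------------------
# kNN classifier
# ---------------------------------------------------------------------------

def knn_score(
    train_genotypes: np.ndarray,
    train_labels: np.ndarray,
    test_genotypes: np.ndarray,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
) -> np.ndarray:
    """Case-fraction kNN scores for test samples over a SNP panel.

    Distance between two samples is the mean absolute allele-count
    difference over panel SNPs non-missing in both; the score is the
    fraction of the k nearest training samples that are cases.  Distance
    ties are broken by training-sample order.  A test sample sharing no
    typed panel SNP with a training sample is at infinite distance from
    it; a test sample with every panel genotype missing scores 0.5.
    """
    train = np.array(train_genotypes, dtype=float)  # copy: MISSING -> NaN below
    test = np.array(test_genotypes, dtype=float)
    if train.ndim != 2 or test.ndim != 2 or train.shape[1] != test.shape[1]:
        raise ValueError("train/test genotype matrices must share the SNP panel")
    if train.shape[1] == 0:
        raise ValueError("empty SNP panel")
    if not (1 <= k_neighbors <= train.shape[0]):
        raise ValueError("k_neighbors must be in [1, n_train]")
    train[train == MISSING] = np.nan
    test[test == MISSING] = np.nan
    is_case = np.asarray(train_labels).astype(bool)

    scores = np.empty(test.shape[0])
    for i in range(test.shape[0]):
        diff = np.abs(test[i][None, :] - train)  # (n_train, panel)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)
            dist = np.nanmean(diff, axis=1)
        dist = np.where(np.isfinite(dist), dist, np.inf)
        if not np.isfinite(dist).any():
            warnings.warn(f"test sample {i} has no typed panel SNPs; scoring 0.5")
            scores[i] = 0.5
            continue
        nearest = np.argsort(dist, kind="stable")[:k_neighbors]
        scores[i] = float(is_case[nearest].mean())
    return scores


# ---------------------------------------------------------------------------
# cross-validated AUC over top-n panels
# ---------------------------------------------------------------------------

def knn_cv_auc(
    dataset: GenotypeDataset,
    ranker,
    panel_sizes=DEFAULT_PANEL_SIZES,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    n_folds: int = 5,
    seed: int = 0,
    fixed_ranking: RankedList | None = None,
    method: str = "",
) -> EvaluationReport:
    """Stratified k-fold CV: rank on training folds, classify the held-out fold.

    ``ranker(dataset, training_mask)`` must return a RankedList computed
    without access to held-out phenotypes (label propagation receives the
    mask and leaves held-out samples unlabeled; the other rankers are
    fitted on the training subset).  Per-sample scores are pooled over
    folds and a single AUC per panel size is computed by the Mann-Whitney
    formulation, with a Hanley-McNeil 95% CI.  A panel size larger than
    the number of SNPs a ranker selected is reported as ``None``
    (unavailable).  ``fixed_ranking`` bypasses per-fold ranking (used by
    the cross-dataset protocol).
    """
    dataset.require_cases_and_controls()
    labeled = dataset.case_mask | dataset.control_mask
    labeled_idx = np.flatnonzero(labeled)
    y = (dataset.phenotypes[labeled_idx] == CASE).astype(int)
    panel_sizes = [int(n) for n in panel_sizes]
    if max(panel_sizes) > dataset.n_snps:
        raise ValueError("panel size exceeds SNP count")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    fold_of = np.full(dataset.n_samples, -1, dtype=int)
    pooled = {n: np.full(len(labeled_idx), np.nan) for n in panel_sizes}
    available = {n: True for n in panel_sizes}

    for fold, (tr, te) in enumerate(skf.split(np.zeros(len(labeled_idx)), y)):
        fold_of[labeled_idx[te]] = fold
        train_mask = np.zeros(dataset.n_samples, dtype=bool)
        train_mask[labeled_idx[tr]] = True
        if fixed_ranking is not None:
            ranking = fixed_ranking
        else:
            ranking = ranker(dataset, train_mask)
        usable = _n_usable(ranking)
        for n in panel_sizes:
            if n > usable:
                available[n] = False
                continue
            panel = ranking.top(n)
            sub = dataset.subset_snps(panel)
            scores = knn_score(
                sub.genotypes[labeled_idx[tr]],
                y[tr],
                sub.genotypes[labeled_idx[te]],
                k_neighbors=min(k_neighbors, len(tr)),
            )
            pooled[n][te] = scores

    auc_by_n: dict[int, tuple[float, float, float] | None] = {}
    n_pos, n_neg = int(y.sum()), int(len(y) - y.sum())
    for n in panel_sizes:
        if not available[n]:
            auc_by_n[n] = None  # ranker selected fewer SNPs than the panel asks
            continue
        auc = mann_whitney_auc(pooled[n], y)
        lo, hi = hanley_mcneil_ci(auc, n_pos, n_neg)
        auc_by_n[n] = (auc, lo, hi)
    return EvaluationReport(
        method=method or getattr(ranker, "__name__", "ranker"),
        panel_sizes=panel_sizes,
        auc_by_n=auc_by_n,
        k_neighbors=k_neighbors,
        n_folds=n_folds,
        seed=seed,
        fold_assignments=fold_of,
    )


def cross_dataset_eval(
    rank_on: GenotypeDataset,
    classify_on: GenotypeDataset,
    ranker,
    panel_sizes=DEFAULT_PANEL_SIZES,
    k_neighbors: int = DEFAULT_K_NEIGHBORS,
    n_folds: int = 5,
    seed: int = 0,
    method: str = "",
) -> EvaluationReport:
    """Rank SNPs on one cohort, evaluate kNN panels on the other.

    The full ranking is computed once on ``rank_on``; panel membership
    and order are fixed by that ranking regardless of ``classify_on``'s
    statistics.  Both datasets must already share the SNP universe (run
    :func:`snplp.io.intersect_snps` first).
    """
    missing = set(rank_on.snp_ids) - set(classify_on.snp_ids)
    if missing:
        raise ValueError(
            f"panel SNPs absent from the classification dataset: {sorted(missing)[:5]}"
        )
    ranking = ranker(rank_on, None)
    return knn_cv_auc(
        classify_on,
        ranker=None,
        panel_sizes=panel_sizes,
        k_neighbors=k_neighbors,
        n_folds=n_folds,
        seed=seed,
        fixed_ranking=ranking,
        method=method or ranking.method,
    )


# ---------------------------------------------------------------------------
# reproducibility and retrieval
# ---------------------------------------------------------------------------

def reproducibility(list_a: RankedList, list_b: RankedList, depth_n: int) -> float:
    """Fraction of SNPs shared by the two top-n lists.

    |top_n(a) intersect top_n(b)| / n; positions within the top-n are
    ignored.
    """
    if depth_n < 1:
        raise ValueError("depth must be >= 1")
    if depth_n > len(list_a) or depth_n > len(list_b):
        raise ValueError("depth exceeds ranking length")
    return len(set(list_a.top(depth_n)) & set(list_b.top(depth_n))) / depth_n


def retrieval_curves(
    ranked: RankedList, truth: SyntheticTruth
) -> tuple[list[tuple[float, float]], list[tuple[float, float]], float, float]:
    """Precision-recall and ROC curves for retrieving the causal SNPs.

    Sweeps the ranking from top to bottom, emitting (recall, precision)
    and (fpr, tpr) at every rank; returns both point lists plus their
    trapezoidal areas (PR AUC, ROC AUC).
    """
    causal = set(truth.causal_snp_ids)
    unknown = causal - set(ranked.snp_ids)
    if unknown:
        raise ValueError(f"causal SNPs missing from the ranking: {sorted(unknown)[:5]}")
    n_pos = len(causal)
    n_neg = len(ranked) - n_pos
    tp = fp = 0
    pr = []
    roc = [(0.0, 0.0)]
    for e in ranked.entries:
        if e.snp_id in causal:
            tp += 1
        else:
            fp += 1
        pr.append((tp / n_pos, tp / (tp + fp)))
        roc.append((fp / n_neg if n_neg else 0.0, tp / n_pos))
    pr_auc = _trapezoid([(0.0, pr[0][1])] + pr)
    roc_auc = _trapezoid(roc)
    return pr, roc, pr_auc, roc_auc


def ranking_roc_auc(ranked: RankedList, positive_ids) -> float:
    """ROC AUC of a ranking against a positive set (rank-based Mann-Whitney)."""
    pos = set(positive_ids)
    labels = np.array([e.snp_id in pos for e in ranked.entries])
    # higher score for earlier ranks
    return mann_whitney_auc(-np.arange(len(labels), dtype=float), labels)


def _trapezoid(points: list[tuple[float, float]]) -> float:
    xs = np.array([p[0] for p in points])
    ys = np.array([p[1] for p in points])
    return float(np.trapezoid(ys, xs))


def _n_usable(ranking: RankedList) -> int:
    from .rankers import n_selected

    return n_selected(ranking)
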