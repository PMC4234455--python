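"""Comparison SNP rankers: genotypic chi-squared, sigmoid-weighted
ReliefF (SWRF), and L1-penalised sparse logistic regression (SLR).

All rankers emit the same :class:`~snplp.ranking.RankedList` as label
propagation and share its tie-break convention (descending score, then
lexicographic SNP id).
"""

from __future__ import annotations

import logging
import warnings

import numpy as np
from scipy import stats

from .dataset import CASE, CONTROL, MISSING, GenotypeDataset
from .ranking import RankedList, make_ranked_list

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# chi-squared
# ---------------------------------------------------------------------------

def chi2_statistics(dataset: GenotypeDataset) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP genotypic Pearson chi-squared statistic and p-value.

    For each SNP the 2x3 case/control-by-genotype contingency table is
    built from non-missing calls; genotype columns with zero total are
    dropped and the degrees of freedom adjusted.  SNPs monomorphic in the
    pooled sample get statistic 0 and p = 1.
    """
    dataset.require_cases_and_controls()
    G = dataset.genotypes
    labeled = dataset.case_mask | dataset.control_mask
    is_case = dataset.case_mask[labeled]
    Gl = G[labeled]
    n_snps = dataset.n_snps
    # per-SNP counts of each genotype state among cases and controls
    counts = np.zeros((2, 3, n_snps))
    for s in range(3):
        hit = Gl == s
        counts[0, s] = (hit & ~is_case[:, None]).sum(axis=0)
        counts[1, s] = (hit & is_case[:, None]).sum(axis=0)
    x2 = np.zeros(n_snps)
    pval = np.ones(n_snps)
    for j in range(n_snps):
        table = counts[:, :, j]
        table = table[:, table.sum(axis=0) > 0]
        if table.shape[1] < 2 or (table.sum(axis=1) == 0).any():
            continue  # monomorphic (or single-class): undefined, p = 1
        row = table.sum(axis=1, keepdims=True)
        col = table.sum(axis=0, keepdims=True)
        expected = row * col / table.sum()
        stat = float(((table - expected) ** 2 / expected).sum())
        df = table.shape[1] - 1
        x2[j] = stat
        pval[j] = float(stats.chi2.sf(stat, df))
    return x2, pval


def chi2_rank(dataset: GenotypeDataset) -> RankedList:
    """Rank SNPs by ascending genotypic chi-squared p-value.

    Ties are broken by larger statistic, then by SNP id.
    """
    x2, pval = chi2_statistics(dataset)
    order = sorted(
        range(dataset.n_snps),
        key=lambda j: (pval[j], -x2[j], dataset.snp_ids[j]),
    )
    from .ranking import RankedEntry

    entries = [
        RankedEntry(
            snp_id=dataset.snp_ids[j],
            snp_score=float(x2[j]),
            state_scores={},
            rank=i + 1,
        )
        for i, j in enumerate(order)
    ]
    return RankedList(entries=entries, method="chi2")


# ---------------------------------------------------------------------------
# SWRF
# ---------------------------------------------------------------------------

def swrf_rank(
    dataset: GenotypeDataset,
    midpoint: float | None = None,
    steepness: float | None = None,
) -> RankedList:
    """Sigmoid-weighted Relief ranking.

    For each ordered pair of distinct labeled samples (i, j), every SNP
    receives a genotype-difference update ``diff = |g_i - g_j| / 2`` (0,
    0.5 or 1 for allele-count differences 0, 1, 2), weighted by a sigmoid
    ``sigma((m - dist(i,j)) / s)`` of the pair distance ``dist(i,j)``,
    the mean genotype difference over the SNPs typed in both samples.
    The sigmoid replaces ReliefF's hard nearest-neighbour cutoff: close
    pairs dominate but no pair is excluded.  A SNP's weight is the
    sigmoid-weighted mean diff over opposite-phenotype pairs minus that
    over same-phenotype pairs, each side normalised by its own sigmoid
    mass so the weight is exactly zero in expectation for a
    phenotype-independent SNP whatever the class balance.  Comparisons at
    SNPs missing in either sample are skipped, contributing to neither
    the sum nor its normaliser.

    ``midpoint`` defaults to the mean pairwise distance and ``steepness``
    to its standard deviation (data-driven defaults; the constants are
    exposed rather than fixed).
    """
    dataset.require_cases_and_controls()
    labeled = dataset.case_mask | dataset.control_mask
    G = dataset.genotypes[labeled].astype(float)
    G[G == MISSING] = np.nan
    y = dataset.phenotypes[labeled]
    n, p = G.shape
    if (y == CASE).sum() < 2 or (y == CONTROL).sum() < 2:
        raise ValueError("SWRF requires at least 2 samples per class")

    observed = ~np.isnan(G)
    miss_w = np.zeros(p)   # opposite-phenotype (miss) accumulators
    miss_norm = np.zeros(p)
    hit_w = np.zeros(p)    # same-phenotype (hit) accumulators
    hit_norm = np.zeros(p)

    # pass 1: pairwise mean genotype distances (for the sigmoid parameters)
    dists = np.zeros((n, n))
    for i in range(n):
        d = np.abs(G[i] - G) / 2.0  # (n, p), NaN where either is missing
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", RuntimeWarning)  # all-NaN rows
            dists[i] = np.nanmean(d, axis=1)
    iu = np.triu_indices(n, k=1)
    pair_d = dists[iu]
    pair_d = pair_d[np.isfinite(pair_d)]
    m = float(np.mean(pair_d)) if midpoint is None else float(midpoint)
    s = float(np.std(pair_d)) if steepness is None else float(steepness)
    if s <= 0 or not np.isfinite(s):
        logger.warning("degenerate pairwise distances; SWRF weights are uniform")
        return make_ranked_list(
            {sid: 0.0 for sid in dataset.snp_ids}, method="swrf",
            params={"midpoint": m, "steepness": s},
        )

    # pass 2: accumulate sigmoid-weighted updates over all ordered pairs
    for i in range(n):
        d = np.abs(G[i] - G) / 2.0
        sig = 1.0 / (1.0 + np.exp(-(m - dists[i]) / s))
        sig[i] = 0.0
        sig[~np.isfinite(dists[i])] = 0.0
        opp = sig * (y != y[i])
        same = sig * (y == y[i])
        same[i] = 0.0
        valid = observed[i][None, :] & observed
        dz = np.where(valid, d, 0.0)
        miss_w += opp @ dz
        miss_norm += opp @ valid
        hit_w += same @ dz
        hit_norm += same @ valid

    with np.errstate(invalid="ignore", divide="ignore"):
        w = np.where(miss_norm > 0, miss_w / miss_norm, 0.0) - np.where(
            hit_norm > 0, hit_w / hit_norm, 0.0
        )
    return make_ranked_list(
        dict(zip(dataset.snp_ids, w)), method="swrf",
        params={"midpoint": m, "steepness": s},
    )


# ---------------------------------------------------------------------------
# SLR
# ---------------------------------------------------------------------------

def slr_rank(
    dataset: GenotypeDataset,
    penalty: float | None = None,
    cv_folds: int = 5,
    seed: int = 0,
) -> RankedList:
    """L1-penalised logistic regression ranking.

    Fits a sparse logistic model of phenotype on all SNPs (missing
    genotypes mean-imputed per SNP for this ranker only) and ranks SNPs by
    descending absolute coefficient.  Zero-coefficient SNPs are
    "unselected": they are placed after all selected SNPs, tie-broken by
    SNP id, so the method can select fewer SNPs than a requested panel
    size.

    ``penalty`` is the inverse regularisation strength C; when omitted it
    is chosen by cross-validated log-loss on a small grid.
    """
    from sklearn.linear_model import LogisticRegression, LogisticRegressionCV

    dataset.require_cases_and_controls()
    labeled = dataset.case_mask | dataset.control_mask
    X = dataset.genotypes[labeled].astype(float)
    X[X == MISSING] = np.nan
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    nan_pos = np.isnan(X)
    X[nan_pos] = np.take(col_mean, np.nonzero(nan_pos)[1])
    y = (dataset.phenotypes[labeled] == CASE).astype(int)

    if penalty is None:
        model = LogisticRegressionCV(
            penalty="l1", solver="liblinear", Cs=np.logspace(-2, 1, 7),
            cv=cv_folds, scoring="neg_log_loss", max_iter=2000,
            random_state=seed,
        )
    else:
        model = LogisticRegression(
            penalty="l1", solver="liblinear", C=float(penalty), max_iter=2000,
            random_state=seed,
        )
    with warnings.catch_warnings():
        # sklearn's penalty= / l1_ratio= API transition
        warnings.simplefilter("ignore", FutureWarning)
        warnings.filterwarnings("ignore", message=".*penalty.*", category=UserWarning)
        model.fit(X, y)
    if not np.all(np.isfinite(model.coef_)):
        raise RuntimeError(f"SLR solver failed at penalty={penalty}")
    coef = model.coef_.ravel()
    c_used = float(model.C_[0]) if penalty is None else float(penalty)

    selected = np.abs(coef) > 0
    order = sorted(
        range(dataset.n_snps),
        key=lambda j: (not selected[j], -abs(coef[j]), dataset.snp_ids[j]),
    )
    from .ranking import RankedEntry

    entries = [
        RankedEntry(
            snp_id=dataset.snp_ids[j],
            snp_score=float(abs(coef[j])),
            state_scores={},
            rank=i + 1,
        )
        for i, j in enumerate(order)
    ]
    return RankedList(
        entries=entries, method="slr",
        params={"C": c_used, "n_selected": int(selected.sum())},
    )


def n_selected(ranked: RankedList) -> int:
    """Number of SNPs a ranker actively selected (positive score)."""
    if "n_selected" in ranked.params:
        return int(ranked.params["n_selected"])
    return len(ranked)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

RANKERS = ("lp", "chi2", "swrf", "slr")


def get_ranker(name: str, **params):
    """Return ``ranker(dataset) -> RankedList`` for a method name.

    Unknown method names and unknown parameter names are rejected.
    """
    from .propagation import PropagationConfig, lp_rank

    if name == "lp":
        known = {"alpha", "tol", "max_iter", "aggregation"}
        _reject_unknown(name, params, known)
        agg = params.pop("aggregation", "max_abs")
        cfg = PropagationConfig(**params)
        return lambda ds, mask=None: lp_rank(ds, cfg, agg, training_mask=mask)
    if name == "chi2":
        _reject_unknown(name, params, set())
        return lambda ds, mask=None: chi2_rank(_masked(ds, mask))
    if name == "swrf":
        _reject_unknown(name, params, {"midpoint", "steepness"})
        return lambda ds, mask=None: swrf_rank(_masked(ds, mask), **params)
    if name == "slr":
        _reject_unknown(name, params, {"penalty", "cv_folds", "seed"})
        return lambda ds, mask=None: slr_rank(_masked(ds, mask), **params)
    raise ValueError(f"unknown ranker {name!r}; options: {RANKERS}")


def _masked(dataset: GenotypeDataset, mask) -> GenotypeDataset:
    return dataset if mask is None else dataset.subset_samples(np.asarray(mask))


def _reject_unknown(name: str, params: dict, known: set) -> None:
    unknown = set(params) - known
    if unknown:
        raise ValueError(f"unknown parameters for {name!r}: {sorted(unknown)}")
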