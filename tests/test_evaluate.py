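import numpy as np
import pytest
from sklearn.metrics import roc_auc_score

from snplp import (
    CASE,
    CONTROL,
    MISSING,
    GenotypeDataset,
    cross_dataset_eval,
    knn_cv_auc,
    knn_score,
    make_ranked_list,
    mann_whitney_auc,
    ranking_roc_auc,
    reproducibility,
    retrieval_curves,
)
from snplp.simulate import SimConfig, SyntheticTruth, generate
from conftest import random_dataset


def _ds(geno, pheno, snp_ids=None):
    geno = np.asarray(geno, dtype=np.int8)
    return GenotypeDataset(
        [f"i{k}" for k in range(geno.shape[0])],
        snp_ids or [f"snp{j}" for j in range(geno.shape[1])],
        geno,
        np.asarray(pheno, dtype=np.int8),
    )


# ---------------------------------------------------------------------------
# AUC primitives
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("seed", range(6))
def test_mann_whitney_auc_matches_sklearn(seed):
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, 80)
    labels[:2] = [0, 1]
    scores = rng.normal(size=80)
    if seed % 2:  # exercise midrank tie handling
        scores = np.round(scores)
    assert mann_whitney_auc(scores, labels) == pytest.approx(
        roc_auc_score(labels, scores), abs=1e-12)


def test_auc_invariant_under_monotone_transform():
    rng = np.random.default_rng(1)
    labels = rng.integers(0, 2, 50)
    labels[:2] = [0, 1]
    scores = rng.normal(size=50)
    a = mann_whitney_auc(scores, labels)
    assert mann_whitney_auc(np.exp(scores), labels) == pytest.approx(a)
    assert mann_whitney_auc(3 * scores - 7, labels) == pytest.approx(a)


# ---------------------------------------------------------------------------
# kNN scorer
# ---------------------------------------------------------------------------


def test_knn_identical_to_case_neighbor():
    train = np.array([[0, 0], [2, 2], [1, 1]])
    labels = np.array([1, 0, 0])
    scores = knn_score(train, labels, np.array([[0, 0]]), k_neighbors=1)
    assert scores[0] == 1.0


def test_knn_degenerate_k_returns_case_fraction():
    rng = np.random.default_rng(4)
    train = rng.integers(0, 3, (10, 3))
    labels = np.array([1] * 4 + [0] * 6)
    scores = knn_score(train, labels, rng.integers(0, 3, (5, 3)), k_neighbors=10)
    assert np.allclose(scores, 0.4)


def test_knn_matches_brute_force_oracle():
    rng = np.random.default_rng(8)
    train = rng.integers(0, 3, (30, 6)).astype(float)
    train[rng.random(train.shape) < 0.1] = MISSING
    labels = rng.integers(0, 2, 30)
    test = rng.integers(0, 3, (12, 6)).astype(float)
    k = 7
    got = knn_score(train, labels, test, k_neighbors=k)
    for i in range(12):
        dists = []
        for t in range(30):
            num = den = 0.0
            for j in range(6):
                if test[i, j] != MISSING and train[t, j] != MISSING:
                    num += abs(test[i, j] - train[t, j])
                    den += 1
            dists.append(num / den if den else np.inf)
        nearest = sorted(range(30), key=lambda t: (dists[t], t))[:k]
        expect = np.mean([labels[t] for t in nearest])
        assert got[i] == pytest.approx(expect)


def test_knn_all_missing_test_sample_scores_half():
    train = np.array([[0], [2]])
    with pytest.warns(UserWarning, match="no typed panel"):
        scores = knn_score(train, np.array([1, 0]),
                           np.array([[MISSING]], dtype=float), k_neighbors=1)
    assert scores[0] == 0.5


def test_knn_input_validation():
    train = np.zeros((4, 2))
    with pytest.raises(ValueError, match="panel"):
        knn_score(train, np.zeros(4), np.zeros((2, 3)), 1)
    with pytest.raises(ValueError, match="k_neighbors"):
        knn_score(train, np.zeros(4), np.zeros((2, 2)), 9)


# ---------------------------------------------------------------------------
# cross-validated AUC
# ---------------------------------------------------------------------------


def _chi2_ranker(ds, mask):
    from snplp.rankers import chi2_rank

    return chi2_rank(ds if mask is None else ds.subset_samples(mask))


def test_cv_auc_perfect_snp():
    rng = np.random.default_rng(10)
    n = 60
    pheno = np.array([CASE] * 30 + [CONTROL] * 30)
    perfect = np.where(pheno == CASE, 2, 0)
    noise = rng.integers(0, 3, (n, 5))
    ds = _ds(np.column_stack([perfect, noise]), pheno)
    rep = knn_cv_auc(ds, _chi2_ranker, panel_sizes=[1], k_neighbors=3, seed=0)
    auc, lo, hi = rep.auc_by_n[1]
    assert auc == 1.0
    assert lo <= auc <= hi


def test_cv_auc_null_near_half():
    rng = np.random.default_rng(11)
    aucs = []
    for seed in range(8):
        geno = rng.integers(0, 3, (60, 10))
        pheno = rng.permutation([CASE] * 30 + [CONTROL] * 30)
        ds = _ds(geno, pheno)
        rep = knn_cv_auc(ds, _chi2_ranker, panel_sizes=[5], k_neighbors=5,
                         seed=seed)
        aucs.append(rep.auc_by_n[5][0])
    assert abs(np.mean(aucs) - 0.5) < 0.08


def test_cv_ranking_never_sees_heldout_phenotypes():
    """The ranker only receives training-fold phenotype information."""
    rng = np.random.default_rng(12)
    ds = random_dataset(rng, n_samples=40, n_snps=6, missing_rate=0.0)
    seen_masks = []

    def spy(dataset, mask):
        assert mask is not None and mask.sum() < dataset.n_samples
        seen_masks.append(mask.copy())
        return _chi2_ranker(dataset, mask)

    knn_cv_auc(ds, spy, panel_sizes=[2], k_neighbors=3, n_folds=5, seed=1)
    assert len(seen_masks) == 5
    # every sample is held out exactly once across folds
    held_out = np.sum([~m for m in seen_masks], axis=0)
    assert np.all(held_out == 1)


def test_cv_marks_unavailable_panels():
    """A ranker selecting fewer SNPs than the panel asks yields a None cell."""
    rng = np.random.default_rng(13)
    ds = random_dataset(rng, n_samples=30, n_snps=8, missing_rate=0.0)

    def sparse_ranker(dataset, mask):
        ranked = _chi2_ranker(dataset, mask)
        ranked.params["n_selected"] = 3
        return ranked

    rep = knn_cv_auc(ds, sparse_ranker, panel_sizes=[2, 5], k_neighbors=3, seed=0)
    assert rep.auc_by_n[2] is not None
    assert rep.auc_by_n[5] is None


def test_cv_reproducible_and_panel_size_guard():
    rng = np.random.default_rng(14)
    ds = random_dataset(rng, n_samples=40, n_snps=6, missing_rate=0.0)
    r1 = knn_cv_auc(ds, _chi2_ranker, panel_sizes=[3], k_neighbors=3, seed=5)
    r2 = knn_cv_auc(ds, _chi2_ranker, panel_sizes=[3], k_neighbors=3, seed=5)
    assert r1.auc_by_n == r2.auc_by_n
    with pytest.raises(ValueError, match="panel size"):
        knn_cv_auc(ds, _chi2_ranker, panel_sizes=[99])


# ---------------------------------------------------------------------------
# cross-dataset protocol
# ---------------------------------------------------------------------------


def test_cross_dataset_identical_equals_fixed_ranking_cv():
    rng = np.random.default_rng(15)
    ds = random_dataset(rng, n_samples=40, n_snps=6, missing_rate=0.0)
    rep = cross_dataset_eval(ds, ds, _chi2_ranker, panel_sizes=[3],
                             k_neighbors=3, seed=2)
    ranking = _chi2_ranker(ds, None)
    ref = knn_cv_auc(ds, None, panel_sizes=[3], k_neighbors=3, seed=2,
                     fixed_ranking=ranking)
    assert rep.auc_by_n == ref.auc_by_n


def test_cross_dataset_panel_fixed_by_ranking_dataset():
    rng = np.random.default_rng(16)
    a = random_dataset(rng, n_samples=30, n_snps=5, missing_rate=0.0)
    b = random_dataset(rng, n_samples=30, n_snps=5, missing_rate=0.0)
    ranking_a = _chi2_ranker(a, None)
    captured = {}

    def fixed(ds_, mask):  # pragma: no cover - not called with fixed_ranking
        raise AssertionError("ranking must come from dataset A")

    rep = knn_cv_auc(b, fixed, panel_sizes=[2], k_neighbors=3, seed=0,
                     fixed_ranking=ranking_a)
    assert rep.auc_by_n[2] is not None


def test_cross_dataset_requires_shared_snps():
    rng = np.random.default_rng(17)
    a = random_dataset(rng, n_samples=20, n_snps=4, missing_rate=0.0)
    b = random_dataset(rng, n_samples=20, n_snps=4, missing_rate=0.0)
    b2 = GenotypeDataset(b.sample_ids, [f"other{j}" for j in range(4)],
                         b.genotypes, b.phenotypes)
    with pytest.raises(ValueError, match="absent"):
        cross_dataset_eval(a, b2, _chi2_ranker, panel_sizes=[2])


def test_cross_dataset_noise_ranking_uninformative():
    """A panel ranked on pure noise carries no signal to a causal dataset."""
    rng = np.random.default_rng(18)
    n = 200
    pheno = np.array([CASE] * 60 + [CONTROL] * 140)
    strong = np.where(pheno == CASE, 2, 0)
    noise_cols = rng.integers(0, 3, (n, 19))
    b = _ds(np.column_stack([strong, noise_cols]), pheno)
    a = _ds(rng.integers(0, 3, (n, 20)),
            rng.permutation(pheno))
    a = GenotypeDataset(a.sample_ids, b.snp_ids, a.genotypes, a.phenotypes)
    aucs = []
    for seed in range(4):
        rep = cross_dataset_eval(a, b, _chi2_ranker, panel_sizes=[2],
                                 k_neighbors=5, seed=seed)
        aucs.append(rep.auc_by_n[2][0])
    # the strong SNP is very unlikely to land in a noise-ranked top-2 panel
    assert abs(np.mean(aucs) - 0.5) < 0.15


# ---------------------------------------------------------------------------
# reproducibility
# ---------------------------------------------------------------------------


def _rl(ids):
    return make_ranked_list({s: -i for i, s in enumerate(ids)})


def test_reproducibility_definition():
    a = _rl(["a", "b", "c", "d"])
    assert reproducibility(a, a, 4) == 1.0
    b = _rl(["e", "f", "g", "h"])
    assert reproducibility(a, b, 4) == 0.0
    c = _rl(["a", "b", "x", "y"])
    assert reproducibility(a, c, 4) == 0.5
    with pytest.raises(ValueError):
        reproducibility(a, c, 0)
    with pytest.raises(ValueError):
        reproducibility(a, c, 9)


def test_reproducibility_ignores_order_within_top_n():
    a = _rl(["a", "b", "c", "d"])
    b = _rl(["c", "a", "b", "d"])
    assert reproducibility(a, b, 3) == 1.0


def test_random_rankings_overlap_n_over_f():
    """Two independent random rankings overlap ~ n/F at depth n."""
    rng = np.random.default_rng(19)
    F, n = 200, 20
    ids = [f"s{i}" for i in range(F)]
    overlaps = [
        reproducibility(_rl(rng.permutation(ids)), _rl(rng.permutation(ids)), n)
        for _ in range(300)
    ]
    se = np.std(overlaps) / np.sqrt(len(overlaps))
    assert abs(np.mean(overlaps) - n / F) < 4 * se + 1e-3


# ---------------------------------------------------------------------------
# retrieval curves
# ---------------------------------------------------------------------------


def _truth(causal, universe):
    return SyntheticTruth(
        causal_snp_ids=list(causal), common_causal_ids=[], rare_causal_ids=[],
        maf={}, odds_ratio={}, baseline_log_odds=0.0, realized_prevalence=0.1,
        noise_snp_ids=[s for s in universe if s not in set(causal)],
    )


def test_retrieval_perfect_ranking():
    ids = [f"s{i}" for i in range(40)]
    ranked = _rl(ids)
    truth = _truth(ids[:5], ids)
    pr, roc, pr_auc, roc_auc = retrieval_curves(ranked, truth)
    assert all(prec == 1.0 for rec, prec in pr[:5])
    assert pr[4] == (1.0, 1.0)
    assert roc_auc == pytest.approx(1.0)


def test_retrieval_reversed_ranking_flips_roc_auc():
    rng = np.random.default_rng(20)
    ids = [f"s{i}" for i in range(60)]
    order = list(rng.permutation(ids))
    truth = _truth(rng.choice(ids, 8, replace=False), ids)
    _, _, _, auc_fwd = retrieval_curves(_rl(order), truth)
    _, _, _, auc_rev = retrieval_curves(_rl(order[::-1]), truth)
    assert auc_fwd + auc_rev == pytest.approx(1.0, abs=1e-9)


def test_retrieval_roc_auc_matches_rank_oracle():
    rng = np.random.default_rng(21)
    ids = [f"s{i}" for i in range(100)]
    order = list(rng.permutation(ids))
    causal = set(rng.choice(ids, 10, replace=False))
    truth = _truth(sorted(causal), ids)
    _, _, _, roc_auc = retrieval_curves(_rl(order), truth)
    labels = [s in causal for s in order]
    ref = roc_auc_score(labels, -np.arange(100, dtype=float))
    assert roc_auc == pytest.approx(ref, abs=1e-12)
    assert ranking_roc_auc(_rl(order), causal) == pytest.approx(ref, abs=1e-12)


def test_retrieval_random_ranking_precision_near_causal_fraction():
    rng = np.random.default_rng(22)
    ids = [f"s{i}" for i in range(200)]
    causal = sorted(rng.choice(ids, 7, replace=False))
    truth = _truth(causal, ids)
    final_prec = []
    for _ in range(100):
        pr, _, pr_auc, _ = retrieval_curves(_rl(rng.permutation(ids)), truth)
        final_prec.append(pr_auc)
    assert abs(np.mean(final_prec) - 7 / 200) < 0.02


def test_retrieval_requires_truth_in_ranking():
    ids = [f"s{i}" for i in range(10)]
    with pytest.raises(ValueError, match="missing"):
        retrieval_curves(_rl(ids), _truth(["ghost"], ids + ["ghost"]))
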