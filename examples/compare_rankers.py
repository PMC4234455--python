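"""Compare the four SNP rankers on how well they retrieve causal SNPs.

Ranks the same synthetic dataset with label propagation, the genotypic
chi-squared test, sigmoid-weighted ReliefF and L1-penalised logistic
regression, then sweeps each ranking to build precision-recall and ROC
curves against the 35 known causal SNPs.
"""

from snplp import (
    PropagationConfig,
    SimConfig,
    chi2_rank,
    generate,
    lp_rank,
    retrieval_curves,
    slr_rank,
    swrf_rank,
)

dataset, truth = generate(SimConfig(seed=1))
print(f"{dataset.n_samples} samples, {dataset.n_snps} SNPs, "
      f"{len(truth.causal_snp_ids)} causal\n")

rankings = {
    "lp (alpha=0.25)": lp_rank(dataset, PropagationConfig(alpha=0.25)),
    "chi2": chi2_rank(dataset),
    "swrf": swrf_rank(dataset),
    "slr": slr_rank(dataset, penalty=1.0),
}

print(f"{'method':<16} {'ROC AUC':>8} {'PR AUC':>8} {'causal in top 50':>17}")
for name, ranked in rankings.items():
    pr, roc, pr_auc, roc_auc = retrieval_curves(ranked, truth)
    top50 = sum(s in set(truth.causal_snp_ids) for s in ranked.top(50))
    print(f"{name:<16} {roc_auc:>8.3f} {pr_auc:>8.3f} {top50:>17}")

print("\nROC AUC is the probability a causal SNP outranks a noise SNP; "
      "PR AUC weights early precision. SLR leaves unselected SNPs in a "
      "tied tail, which lowers its full-list areas.")
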