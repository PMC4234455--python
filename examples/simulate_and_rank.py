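"""Generate a synthetic case/control GWAS and rank its SNPs by label
propagation.

The generator draws 1,000 samples by 1,000 SNPs: 10 common causal SNPs
(weak odds ratios), 25 rare causal SNPs (strong odds ratios), 965 noise
SNPs, and a liability-threshold phenotype with 13.3% cases.  Label
propagation diffuses the case/control labels over the bipartite
sample/SNP-state graph; the converged state-node scores rank the SNPs.
"""

from snplp import PropagationConfig, SimConfig, generate, lp_rank

dataset, truth = generate(SimConfig(seed=1))
print(f"dataset: {dataset.n_samples} samples x {dataset.n_snps} SNPs, "
      f"{dataset.n_cases} cases ({truth.realized_prevalence:.1%})")

ranked = lp_rank(dataset, PropagationConfig(alpha=0.25))
print(f"label propagation converged in {ranked.params['iterations']} sweeps\n")

causal = set(truth.causal_snp_ids)
print("top 15 SNPs (score = max |state-node label|; * marks true causal):")
for e in ranked.entries[:15]:
    mark = "*" if e.snp_id in causal else " "
    print(f"  {e.rank:>4}  {e.snp_id}{mark}  score={e.snp_score:.4f}  "
          f"OR={truth.odds_ratio[e.snp_id]:.2f}  MAF={truth.maf[e.snp_id]:.4f}")

n_top50 = sum(e.snp_id in causal for e in ranked.entries[:50])
print(f"\n{n_top50} of the top 50 SNPs are truly causal "
      f"(35 causal among 1,000; chance would give ~1.75).")
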