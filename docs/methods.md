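# Methods

## Bipartite encoding

A case/control genotype dataset (N samples × F SNPs, additive coding
0/1/2 with missing calls) is encoded as a bipartite graph: sample nodes
V, and up to three state nodes per SNP in U — one per genotype state
actually observed.  A unit edge joins sample v to state node u exactly
when v's non-missing call at that SNP equals u's state, so each sample
touches at most one state node per SNP and a missing call contributes
nothing.  Degrees are d(v) = number of typed SNPs for v and d(u) =
number of carriers of the state.

Zero-degree nodes are pruned rather than regularised: the symmetric
normalisation D^{-1/2} is undefined at degree zero, and an unobserved
state carries no evidence.  Pruned states are still reported in rankings
with score 0; samples with every call missing are dropped with a
warning.  Node order is deterministic (samples in dataset order, states
by SNP column then state), so all outputs are reproducible across
platforms.

## Propagation model

Labels y ∈ {−1, 0, +1} (training controls, unknowns, training cases;
state nodes always start at 0) are relaxed to real scores f minimising

Q(f) = Σ_{(v,u)∈E} w(v,u) (f(v)/√d(v) − f(u)/√d(u))² + μ [Σ_v (f(v)−y(v))² + Σ_u (f(u)−y(u))²].

With S the symmetric block of B = D_V^{-1/2} W D_U^{-1/2} and
α = 1/(1+μ), the unique minimiser is f* = (1−α)(I−αS)^{-1}Y.  The
solver uses simultaneous (Jacobi) sweeps

f_{t+1}(V) = (1−α) y(V) + α B f_t(U),  f_{t+1}(U) = (1−α) y(U) + α Bᵀ f_t(V),

whose error contracts at least geometrically with ratio α in the 2-norm
because ‖S‖₂ ≤ 1 (the largest singular value of B is 1, attained at the
√degree vector).  The V- and U-updates use B and its transpose
respectively; only the transposed form is dimensionally consistent and
matches the closed form, which the test suite verifies on hundreds of
random graphs.  A dense closed-form solver (capped at 5,000 nodes) is
kept solely as the oracle for those checks.

### Parameters

- **α ∈ [0, 1)** — diffusion/fit balance; ranking default 0.25, which
  weights label fidelity strongly while still sharing information
  through the graph.  α = 0 returns the initial labels; α → 1
  flattens scores toward uninformative uniformity.  μ is not exposed
  separately (μ = (1−α)/α).
- **tol = 1e-6** — L∞ change over all node scores per sweep; with the
  geometric contraction this resolves the fixed point to well below
  ranking resolution.  **max_iter = 1000**; non-convergence is flagged
  on the result, not raised.
- **Aggregation** of a SNP's three state scores into one ranking score:
  default max-absolute (rewards any strongly associated state, e.g. a
  recessive minor homozygote), with mean-absolute and signed-range as
  alternatives.  How the three state scores should be reduced to one
  SNP score is genuinely open; max-abs is this package's choice and is
  reported with the ranking, and ties are broken lexicographically.

### Score range

With labels in {−1, 0, +1}, scores stay in [−1, +1] on genotype-derived
graphs, where every sample's degree is the (large) number of typed SNPs.
This is a property of realistic degree profiles, not of the operator:
on degree-skewed graphs (a high-degree state node fed by degree-1
samples) the raw state score can exceed 1 — a 9-samples-on-one-state
construction converges to f(u) = 3α/(1+α) ≈ 1.42 at α = 0.9 — while the
degree-scaled scores f(x)/√d(x) always stay within max|y|.  The test
suite asserts the raw bound on genotype graphs and the scaled bound in
general.

## Control rankers

- **chi2** — genotypic Pearson test on the 2×3 case/control × state
  table; empty state columns are dropped with the degrees of freedom
  adjusted; monomorphic SNPs rank last at p = 1.  Ranking is by
  ascending p (then larger statistic, then id).
- **swrf** — sigmoid-weighted Relief.  For every ordered sample pair,
  each SNP accrues the pair's genotype difference (0/0.5/1), weighted by
  σ((m − dist)/s) of the pair's mean genotype distance; a SNP's weight
  is the weighted mean difference over opposite-phenotype pairs minus
  that over same-phenotype pairs, each side normalised by its own
  sigmoid mass.  The separate normalisation makes the null expectation
  exactly zero regardless of class balance (a joint normalisation leaves
  a positive bias of order 1/N from the pair-count imbalance).  The
  sigmoid constants are data-driven — midpoint m = mean pairwise
  distance, steepness s = its standard deviation — and exposed; they are
  this package's parameterisation of the sigmoid-neighbourhood idea, not
  a numerical reconstruction of any particular published constant set.
  Missing comparisons are skipped on both sides of the ratio.
- **slr** — L1-penalised logistic regression on all SNPs jointly
  (missing calls mean-imputed for this ranker only), fitted with
  scikit-learn's liblinear solver; penalty chosen by 5-fold
  cross-validated log-loss unless given.  SNPs rank by |coefficient|;
  zero-coefficient SNPs are explicitly "unselected" and placed after all
  selected ones, so panels larger than the selection are reported as
  unavailable rather than padded.  A consequence worth knowing:
  full-list retrieval areas for slr are depressed by the tied unselected
  tail even when the selected set is excellent.

## Synthetic GWAS generator

The generator emulates a 1,000 × 1,000 case/control design: 10 common
causal SNPs (MAF ~ U[0.05, 0.5], per-allele OR ~ U[1.05, 1.5]), 25 rare
causal SNPs (MAF ~ U[0.0001, 0.01], OR ~ U[2, 10]), 965 noise SNPs
(MAF ~ U[0.0001, 0.5], OR = 1).  Genotypes are Hardy–Weinberg draws,
independent across SNPs.  Genetic liability is additive on the log-odds
scale: Σ g_i · log OR_i.

Phenotype assignment defaults to a deterministic liability threshold:
the fraction of individuals with the highest liability equal to the
target prevalence (13.3%) are cases, ties broken by a seeded random
jitter, so the realized prevalence is exact by construction.  A
stochastic alternative (`phenotype_model="logistic"`) draws status
Bernoulli from logistic(baseline + liability), with the baseline
calibrated by Monte-Carlo bisection so the expected prevalence hits the
target; this is mathematically a liability threshold plus logistic
environmental noise.  The deterministic threshold is the default
because it reads "threshold model" literally, pins the stated prevalence
exactly, and at this sample size gives all rankers the retrieval
strength the design intends; the logistic variant, whose per-genotype
noise roughly halves the effective signal at 133 cases, is retained for
sensitivity analysis.

All randomness flows from one seed through split substreams (effect
sizes, genotypes, phenotypes, causal placement), so changing, say, the
sample count does not perturb the drawn MAFs.

What the generator does **not** emulate: linkage disequilibrium between
SNPs, population structure, genotyping error, covariates.  Passing
tests on this data therefore demonstrate correctness of the algorithms
under independence, not robustness to correlated markers or stratified
cohorts — on real data, LD will spread a causal signal over neighbours
and stratification can inflate every ranker.

## Evaluation protocols

- **Cross-validated panel AUC** — stratified 5-fold split (seeded);
  the ranking is recomputed per fold with held-out phenotypes withheld
  (label propagation keeps held-out samples in the graph as unlabeled
  nodes — the transductive setting); a kNN classifier over the top-n
  panel scores the held-out fold; scores are pooled and a single AUC per
  n is computed by the Mann–Whitney midrank formulation.  kNN distance
  is the mean absolute allele-count difference over panel SNPs typed in
  both samples (missing-robust); k defaults to 11 (odd, avoids vote
  ties) — the protocol leaves k, the distance and the CI method open,
  so these are package choices, stated in every report.  95% CIs use
  the Hanley–McNeil standard error.  The cross-dataset variant fixes
  the panel from one cohort's ranking and evaluates entirely within the
  other.
- **Reproducibility** — |top_n(A) ∩ top_n(B)| / n; positions inside the
  top-n are ignored.  Two independent random rankings average n/F, the
  diagonal reference line in the plots.
- **Retrieval curves** — sweep the ranking, emit precision/recall and
  FPR/TPR at every rank, report trapezoidal areas.

## Numerical and degenerate-input choices

- Monomorphic SNPs: chi2 p = 1 (ranked last); SWRF weight 0; slr
  coefficient 0 (unselected); LP gives the single state node a score
  determined by diffusion alone, typically near the grand case/control
  balance.
- A test sample with every panel SNP missing scores 0.5 (coin flip)
  with a warning; kNN distance ties break by training-sample order.
- SWRF with all pairwise distances identical (degenerate sigmoid) falls
  back to uniform zero weights with a warning.
- All rankings break score ties by SNP id; every ranking contains each
  input SNP exactly once.

## Known limitations

- No LD-aware or stratification-corrected edge weighting; the incidence
  weight field is general, but only unit weights are produced.
- The closed-form solver is deliberately dense and capped; it exists as
  an oracle, not a production path.
- SWRF is O(N²F); fine at the simulated scale (≈20 s at 1,000 × 1,000),
  quadratic beyond it.
- Inductive (out-of-graph) prediction is out of scope: predictions are
  only defined for samples present during propagation.
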