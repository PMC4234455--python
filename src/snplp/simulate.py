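"""Synthetic case/control GWAS generator.

Emulates a study design with 1,000 samples by 1,000 independent SNPs:
35 causal SNPs — 10 common (MAF uniform on [0.05, 0.5], per-allele odds
ratio on [1.05, 1.5]) and 25 rare (MAF on [0.0001, 0.01], odds ratio on
[2, 10]) — plus 965 noise SNPs whose MAFs range from rare to common with
no phenotype effect.  Genotypes are drawn under Hardy-Weinberg
proportions independently across SNPs (no linkage disequilibrium).
Disease follows an additive liability model on the log-odds scale: each
causal allele adds log(OR).  By default status is assigned by a
deterministic threshold: the 13.3% of individuals with the highest
genetic liability are the cases (ties broken at random), which pins the
prevalence exactly.  A stochastic variant instead draws status Bernoulli
from the logistic of (calibrated baseline + liability), equivalent to a
threshold on liability plus logistic environmental noise.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .dataset import CASE, CONTROL, GenotypeDataset

_CALIBRATION_MC_SAMPLES = 20000
_CALIBRATION_SEED = 20240811  # internal stream; independent of the user seed


@dataclass
class SimConfig:
    """Generator settings; defaults are the emulated study design."""

    n_samples: int = 1000
    n_snps: int = 1000
    n_common_causal: int = 10
    common_maf_range: tuple[float, float] = (0.05, 0.5)
    common_or_range: tuple[float, float] = (1.05, 1.5)
    n_rare_causal: int = 25
    rare_maf_range: tuple[float, float] = (0.0001, 0.01)
    rare_or_range: tuple[float, float] = (2.0, 10.0)
    noise_maf_range: tuple[float, float] = (0.0001, 0.5)
    target_prevalence: float = 0.133
    phenotype_model: str = "threshold"  # "threshold" or "logistic"
    seed: int = 0

    def __post_init__(self) -> None:
        for lo, hi in (self.common_maf_range, self.rare_maf_range, self.noise_maf_range):
            if not (0.0 < lo <= hi <= 0.5):
                raise ValueError("MAF ranges must lie within (0, 0.5]")
        if self.n_common_causal + self.n_rare_causal > self.n_snps:
            raise ValueError("causal SNP count exceeds n_snps")
        if not (0.0 < self.target_prevalence < 1.0):
            raise ValueError("target_prevalence must be in (0, 1)")
        if self.phenotype_model not in ("threshold", "logistic"):
            raise ValueError("phenotype_model must be 'threshold' or 'logistic'")
        if self.phenotype_model == "threshold":
            n_cases = round(self.n_samples * self.target_prevalence)
            if not (0 < n_cases < self.n_samples):
                raise ValueError(
                    "target_prevalence unreachable: it must round to at least "
                    "one case and one control at this n_samples"
                )

    @property
    def n_causal(self) -> int:
        return self.n_common_causal + self.n_rare_causal


@dataclass
class SyntheticTruth:
    """Ground truth accompanying a generated dataset."""

    causal_snp_ids: list[str]
    common_causal_ids: list[str]
    rare_causal_ids: list[str]
    maf: dict[str, float]
    odds_ratio: dict[str, float]
    baseline_log_odds: float
    realized_prevalence: float
    noise_snp_ids: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "causal_snp_ids": self.causal_snp_ids,
            "common_causal_ids": self.common_causal_ids,
            "rare_causal_ids": self.rare_causal_ids,
            "maf": self.maf,
            "odds_ratio": self.odds_ratio,
            "baseline_log_odds": self.baseline_log_odds,
            "realized_prevalence": self.realized_prevalence,
            "noise_snp_ids": self.noise_snp_ids,
        }
        Path(path).write_text(json.dumps(payload, indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "SyntheticTruth":
        d = json.loads(Path(path).read_text())
        return cls(**d)


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def calibrate_baseline(
    mafs: np.ndarray,
    odds_ratios: np.ndarray,
    target_prevalence: float,
    tol: float = 1e-8,
) -> float:
    """Baseline log-odds such that expected prevalence hits the target.

    Solves E[logistic(b + sum_i g_i log OR_i)] = target by bisection, the
    expectation taken over Hardy-Weinberg genotypes and estimated by
    Monte Carlo with a fixed internal seed (so the result is a
    deterministic function of the inputs).  Monotone increasing in the
    target.
    """
    mafs = np.asarray(mafs, dtype=float)
    odds_ratios = np.asarray(odds_ratios, dtype=float)
    if not (np.all(np.isfinite(mafs)) and np.all(np.isfinite(odds_ratios))):
        raise ValueError("mafs and odds_ratios must be finite")
    if len(mafs) == 0:
        return float(np.log(target_prevalence / (1.0 - target_prevalence)))
    rng = np.random.default_rng(_CALIBRATION_SEED)
    g = rng.binomial(2, mafs, size=(_CALIBRATION_MC_SAMPLES, len(mafs)))
    burden = g @ np.log(odds_ratios)

    def prev(b: float) -> float:
        return float(np.mean(_sigmoid(b + burden)))

    lo, hi = -50.0, 50.0
    if not (prev(lo) < target_prevalence < prev(hi)):
        raise ValueError("target prevalence unreachable in the bisection bracket")
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if prev(mid) < target_prevalence:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def generate(cfg: SimConfig | None = None) -> tuple[GenotypeDataset, SyntheticTruth]:
    """Draw a synthetic dataset plus its ground truth.

    Deterministic given ``cfg.seed``; independent random streams are
    spawned for effect sizes, genotypes and phenotypes so that, e.g.,
    changing n_samples does not perturb the drawn MAFs.
    """
    cfg = cfg or SimConfig()
    ss = np.random.SeedSequence(cfg.seed)
    rng_effects, rng_geno, rng_pheno, rng_place = (
        np.random.default_rng(s) for s in ss.spawn(4)
    )

    n_noise = cfg.n_snps - cfg.n_causal
    mafs = np.concatenate([
        rng_effects.uniform(*cfg.common_maf_range, size=cfg.n_common_causal),
        rng_effects.uniform(*cfg.rare_maf_range, size=cfg.n_rare_causal),
        rng_effects.uniform(*cfg.noise_maf_range, size=n_noise),
    ])
    odds = np.concatenate([
        rng_effects.uniform(*cfg.common_or_range, size=cfg.n_common_causal),
        rng_effects.uniform(*cfg.rare_or_range, size=cfg.n_rare_causal),
        np.ones(n_noise),
    ])
    # scatter causal SNPs across the panel so column position carries no signal
    perm = rng_place.permutation(cfg.n_snps)
    mafs, odds = mafs[perm], odds[perm]
    causal = np.zeros(cfg.n_snps, dtype=bool)
    causal[np.flatnonzero(perm < cfg.n_causal)] = True

    genotypes = rng_geno.binomial(2, mafs, size=(cfg.n_samples, cfg.n_snps)).astype(np.int8)

    baseline = calibrate_baseline(mafs[causal], odds[causal], cfg.target_prevalence)
    liability = genotypes[:, causal].astype(float) @ np.log(odds[causal])
    if cfg.phenotype_model == "threshold":
        # the highest-liability fraction are cases; random jitter breaks ties
        n_cases = round(cfg.n_samples * cfg.target_prevalence)
        order = np.lexsort((rng_pheno.random(cfg.n_samples), -liability))
        status = np.zeros(cfg.n_samples, dtype=bool)
        status[order[:n_cases]] = True
    else:
        risk = _sigmoid(baseline + liability)
        status = rng_pheno.random(cfg.n_samples) < risk
    phenotypes = np.where(status, CASE, CONTROL).astype(np.int8)

    width = len(str(cfg.n_snps))
    snp_ids = [f"snp{j:0{width}d}" for j in range(1, cfg.n_snps + 1)]
    sample_ids = [f"s{i:04d}" for i in range(1, cfg.n_samples + 1)]
    dataset = GenotypeDataset(
        sample_ids=sample_ids,
        snp_ids=snp_ids,
        genotypes=genotypes,
        phenotypes=phenotypes,
        snp_meta=pd.DataFrame({"chrom": ["1"] * cfg.n_snps,
                               "pos": np.arange(1, cfg.n_snps + 1) * 1000}),
    )
    causal_ids = [snp_ids[j] for j in np.flatnonzero(causal)]
    common_ids = [snp_ids[j] for j in np.flatnonzero(perm < cfg.n_common_causal)]
    rare_ids = [s for s in causal_ids if s not in set(common_ids)]
    truth = SyntheticTruth(
        causal_snp_ids=causal_ids,
        common_causal_ids=common_ids,
        rare_causal_ids=rare_ids,
        maf={snp_ids[j]: float(mafs[j]) for j in range(cfg.n_snps)},
        odds_ratio={sid: float(odds[j]) for j, sid in enumerate(snp_ids)},
        baseline_log_odds=float(baseline),
        realized_prevalence=float(status.mean()),
        noise_snp_ids=[snp_ids[j] for j in np.flatnonzero(~causal)],
    )
    return dataset, truth
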