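"""Synthetic genotype/covariate/phenotype cohorts.

Emulates the statistical structure of a small pharmacogenomics cohort:
~178 patients with a ~137:41 responder/non-responder imbalance, 22
autosomes of additively coded SNPs with minor-allele frequencies drawn
from [0.01, 0.5], optional linkage-disequilibrium blocks, clinical
covariates (gender, smoker, ECOG, histology, treatment, arm), and a
binary phenotype generated from a logistic model over a small set of
planted causal SNPs.

Genotypes are sampled under Hardy-Weinberg equilibrium: each of the two
haplotypes carries the minor allele independently with probability MAF.
LD blocks share a latent Gaussian per haplotype with compound-symmetric
correlation rho; thresholding the latent at the MAF quantile preserves
each SNP's marginal frequency while inducing correlation between
neighbours.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

from .data_model import AUTOSOMES, CovariateSchema, GenotypeDataset


class CalibrationError(RuntimeError):
    """The target class fraction cannot be reached by shifting the intercept."""


#: covariate coding mirrors a typical NSCLC trial table:
#: gender 1=male/2=female, smoker 1=yes/2=no, ECOG performance 0/1/2,
#: histology 1=ADC/2=SCC/3=LCC/4=other, treatment 1=doce+cis/2=gemci+cis/3=doce,
#: arm 0=control/1=biomarker-directed.
DEFAULT_COVARIATE_SCHEMAS = (
    CovariateSchema("gender", "binary", (1, 2)),
    CovariateSchema("smoker", "binary", (1, 2)),
    CovariateSchema("ecog", "ordinal", (0, 1, 2)),
    CovariateSchema("histology", "categorical", (1, 2, 3, 4)),
    CovariateSchema("treatment", "categorical", (1, 2, 3)),
    CovariateSchema("arm", "binary", (0, 1)),
)

_COVARIATE_PROBS = {
    "gender": ((1, 2), (0.78, 0.22)),
    "smoker": ((1, 2), (0.94, 0.06)),
    "ecog": ((0, 1, 2), (0.34, 0.65, 0.01)),
    "histology": ((1, 2, 3, 4), (0.56, 0.36, 0.05, 0.03)),
    "treatment": ((1, 2, 3), (0.69, 0.25, 0.06)),
    "arm": ((0, 1), (0.53, 0.47)),
}


@dataclass
class SimulationConfig:
    """Parameters of one synthetic cohort.

    ``causal_snps`` entries are (chromosome, within-chromosome index,
    effect log-odds beta).  The intercept is auto-calibrated so the
    realized class-1 fraction matches ``class_fraction``.
    """

    n_samples: int = 178
    n_snps_per_chromosome: tuple = tuple(50 for _ in AUTOSOMES)
    maf_range: tuple = (0.01, 0.5)
    ld_block_size: int = 1
    ld_rho: float = 0.0
    causal_snps: list = field(default_factory=list)
    intercept: float | None = None
    covariate_effects: dict = field(default_factory=dict)
    class_fraction: float = 41 / 178
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if len(self.n_snps_per_chromosome) != len(AUTOSOMES):
            raise ValueError("n_snps_per_chromosome must have 22 entries")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")
        if not 0.0 < self.class_fraction < 1.0:
            raise ValueError("class_fraction must lie in (0, 1)")
        if self.ld_block_size < 1:
            raise ValueError("ld_block_size must be >= 1")
        if self.ld_block_size > 1 and any(
            0 < n < self.ld_block_size for n in self.n_snps_per_chromosome
        ):
            raise ValueError("ld_block_size exceeds a chromosome's SNP count")
        for chrom, idx, _beta in self.causal_snps:
            if chrom not in AUTOSOMES:
                raise ValueError(f"causal SNP on invalid chromosome {chrom}")
            if not 0 <= idx < self.n_snps_per_chromosome[chrom - 1]:
                raise ValueError(f"causal SNP index {idx} out of range on chr{chrom}")


def _simulate_chromosome(rng, n, n_snps, mafs, block_size, rho):
    """HWE genotype codes for one chromosome, with optional LD blocks."""
    if n_snps == 0:
        return np.empty((n, 0))
    thresholds = norm.ppf(mafs)
    geno = np.zeros((n, n_snps))
    for _hap in range(2):
        if block_size <= 1 or rho == 0.0:
            z = rng.standard_normal((n, n_snps))
        else:
            z = np.empty((n, n_snps))
            start = 0
            while start < n_snps:
                b = min(block_size, n_snps - start)
                shared = rng.standard_normal((n, 1))
                noise = rng.standard_normal((n, b))
                z[:, start : start + b] = (
                    math.sqrt(rho) * shared + math.sqrt(1.0 - rho) * noise
                )
                start += b
        geno += (z < thresholds[None, :]).astype(float)
    return geno


def simulate_genotypes(config: SimulationConfig) -> GenotypeDataset:
    """Generate an unlabelled genotype cohort (with covariates)."""
    rng = np.random.default_rng(config.seed)
    lo, hi = config.maf_range
    blocks, meta = [], []
    for chrom, n_snps in zip(AUTOSOMES, config.n_snps_per_chromosome):
        mafs = rng.uniform(lo, hi, size=n_snps)
        blocks.append(
            _simulate_chromosome(
                rng, config.n_samples, n_snps, mafs,
                config.ld_block_size, config.ld_rho,
            )
        )
        for j in range(n_snps):
            meta.append(
                {
                    "snp_id": f"chr{chrom}_snp{j}",
                    "chrom": chrom,
                    "pos": 10_000 * (j + 1),
                    "maf": mafs[j],
                }
            )
    X = np.hstack(blocks)
    if config.missing_rate > 0:
        miss = rng.random(X.shape) < config.missing_rate
        X = np.where(miss, np.nan, X)
    covariates = _simulate_covariates(rng, config.n_samples)
    return GenotypeDataset(
        X=X,
        snp_map=pd.DataFrame(meta),
        covariates=covariates,
        sample_ids=[f"S{i:04d}" for i in range(config.n_samples)],
    )


def _simulate_covariates(rng, n) -> pd.DataFrame:
    cols = {}
    for name, (codes, probs) in _COVARIATE_PROBS.items():
        cols[name] = rng.choice(codes, size=n, p=probs)
    return pd.DataFrame(cols, dtype=float)


def _causal_column_indices(config: SimulationConfig) -> np.ndarray:
    offsets = np.cumsum([0] + list(config.n_snps_per_chromosome))
    return np.asarray(
        [offsets[chrom - 1] + idx for chrom, idx, _ in config.causal_snps], dtype=int
    )


def simulate_phenotype(genotypes: GenotypeDataset, config: SimulationConfig) -> np.ndarray:
    """Draw binary labels from a logistic model over planted causal SNPs.

    P(y=1) = logistic(b0 + sum beta * code + covariate terms).  The
    intercept b0 is found by bisection on the *realized* class-1 count
    for one fixed draw of uniforms, so the generated cohort hits the
    target fraction almost exactly; an explicitly set intercept skips
    calibration.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 1]))
    n = genotypes.n_samples
    lin = np.zeros(n)
    if config.causal_snps:
        cols = _causal_column_indices(config)
        betas = np.asarray([b for _, _, b in config.causal_snps])
        G = np.nan_to_num(genotypes.X[:, cols], nan=0.0)
        lin += G @ betas
    for name, beta in config.covariate_effects.items():
        lin += beta * genotypes.covariates[name].to_numpy(dtype=float)

    u = rng.random(n)
    if config.intercept is not None:
        p = 1.0 / (1.0 + np.exp(-(config.intercept + lin)))
        return (u < p).astype(int)

    target = config.class_fraction

    def realized(b0):
        p = 1.0 / (1.0 + np.exp(-(b0 + lin)))
        return float(np.mean(u < p))

    lo_b, hi_b = -30.0, 30.0
    if realized(lo_b) > target or realized(hi_b) < target:
        raise CalibrationError(
            f"class fraction {target} unreachable by intercept calibration"
        )
    for _ in range(200):
        mid = 0.5 * (lo_b + hi_b)
        if realized(mid) < target:
            lo_b = mid
        else:
            hi_b = mid
    b0 = hi_b
    p = 1.0 / (1.0 + np.exp(-(b0 + lin)))
    y = (u < p).astype(int)
    if abs(y.mean() - target) > 0.02 + 1.0 / n:
        raise CalibrationError(
            f"calibrated fraction {y.mean():.3f} misses target {target:.3f}"
        )
    return y


def simulate_cohort(config: SimulationConfig) -> GenotypeDataset:
    """Full labelled synthetic cohort (genotypes + covariates + labels)."""
    ds = simulate_genotypes(config)
    ds.y = simulate_phenotype(ds, config)
    ds.validate()
    return ds
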