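import numpy as np
import pandas as pd
import pytest

from chromstab import GenotypeDataset, SimulationConfig, simulate_cohort


def make_dataset(X, chroms=None, y=None, covariates=None):
    """Small helper: wrap a raw matrix into a GenotypeDataset."""
    X = np.asarray(X, dtype=float)
    p = X.shape[1]
    chroms = chroms if chroms is not None else [1] * p
    snp_map = pd.DataFrame(
        {
            "snp_id": [f"snp{i}" for i in range(p)],
            "chrom": chroms,
            "pos": [1000 * (i + 1) for i in range(p)],
        }
    )
    return GenotypeDataset(X=X, snp_map=snp_map, y=y, covariates=covariates)


@pytest.fixture(scope="session")
def two_chrom_cohort():
    """n=200 cohort on 2 chromosomes with 2 planted causal SNPs."""
    cfg = SimulationConfig(
        n_samples=200,
        n_snps_per_chromosome=tuple([25, 25] + [0] * 20),
        maf_range=(0.2, 0.4),
        causal_snps=[(1, 0, np.log(3)), (2, 3, np.log(3))],
        seed=11,
    )
    return simulate_cohort(cfg)


@pytest.fixture(scope="session")
def null_cohort():
    """n=200 cohort with no causal SNPs (labels independent of genotypes)."""
    cfg = SimulationConfig(
        n_samples=200,
        n_snps_per_chromosome=tuple([25, 25] + [0] * 20),
        maf_range=(0.2, 0.4),
        seed=13,
    )
    return simulate_cohort(cfg)


REDUCED_GRID = {
    "clf__C": [0.1, 1.0],
    "clf__n_estimators": [30],
    "clf__n_neighbors": [5],
    "fs__C": [100],
}
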