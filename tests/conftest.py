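import numpy as np
import pandas as pd
import pytest

from growthgwas.genotypes import GenotypeMatrix
from growthgwas.simulate import SimulationConfig, simulate_dataset

# Table-style reference inputs used across tests: population mean weights (kg)
# and SDs at 0/6/12/18 months for ~800 beef cattle, and the reference
# parameter estimates obtained from them.
MEAN_AGES = np.array([0.0, 6.0, 12.0, 18.0])
MEAN_WEIGHTS = np.array([38.79, 208.68, 398.70, 520.10])
WEIGHT_SDS = np.array([6.21, 39.48, 56.21, 73.18])
REPORTED = {
    "gompertz": (617.900, 2.740, 0.153),
    "logistic": (551.000, 9.304, 0.273),
    "brody": (1458.500, 0.976, 0.024),
}


@pytest.fixture(scope="session")
def small_sim():
    """300 animals x 800 SNPs with 5 pleiotropic QTL; shared across tests."""
    cfg = SimulationConfig(n_individuals=300, n_snps=800, n_qtl=5,
                           missing_rate=0.01, seed=3)
    genos, arch, records = simulate_dataset(cfg)
    return cfg, genos, arch, records


def balding_nichols_genotypes(rng, n, m, maf_low=0.1, maf_high=0.5):
    """Plain unstructured genotype draw for GWAS calibration tests."""
    p = rng.uniform(maf_low, maf_high, size=m)
    return rng.binomial(2, p, size=(n, m)).astype(float)


def polygenic_trait(rng, G, h2):
    """Trait with polygenic architecture over all SNPs at heritability h2."""
    p = G.mean(axis=0) / 2.0
    sd = np.sqrt(2 * p * (1 - p))
    sd[sd == 0] = 1.0
    Z = (G - 2 * p) / sd
    g = Z @ rng.standard_normal(G.shape[1]) / np.sqrt(G.shape[1])
    g = (g - g.mean())
    gv = np.var(g, ddof=1)
    if gv > 0 and h2 > 0:
        g *= np.sqrt(h2 / gv)
    else:
        g[:] = 0.0
    e = rng.standard_normal(G.shape[0]) * np.sqrt(1 - h2)
    return g + e, g


def as_genotype_matrix(G):
    m = G.shape[1]
    snp_map = pd.DataFrame({"chrom": 1, "pos": np.arange(1, m + 1) * 1000,
                            "snp_id": [f"s{j}" for j in range(m)]})
    return GenotypeMatrix(matrix=G, snp_map=snp_map)
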