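"""Synthetic genotype/phenotype generator for the longitudinal-GWAS pipeline.

Emulates the structure of a beef-cattle association study: a structured
population of diploid animals genotyped at independent biallelic SNPs,
growth described per animal by a Gompertz curve whose parameters (A, b, K)
carry pleiotropic QTL effects plus a kinship-structured polygenic
background, and body weight observed at a few ages with age-specific
measurement noise and additive fixed effects (breed, birth year, birth
month).

Population structure follows a Balding-Nichols scheme: each SNP draws an
ancestral frequency uniformly inside ``maf_range``, and each subpopulation
perturbs it with a Beta distribution whose concentration is set by an
Fst-like divergence parameter.  All randomness flows from one master seed
through deterministic per-stage child seeds, so partial reruns reproduce.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import GenotypeMatrix
from .growth import predict_weight

__all__ = ["SimulationConfig", "TrueArchitecture", "simulate_genotypes",
           "simulate_architecture", "simulate_weights", "simulate_dataset"]

# Default scale: population means of the Gompertz parameters for a mature
# beef breed (~618 kg asymptote, maturity rate 0.153/month) and per-age
# weight-measurement SDs calibrated by first-order error propagation so the
# total per-age weight SDs land near 6.2/39.5/56.2/73.2 kg at 0/6/12/18 mo.
_PARAM_MEANS = (617.9, 2.74, 0.153)
_PARAM_CVS = (0.08, 0.04, 0.08)
_RESID_SD = {0.0: 3.0, 6.0: 30.0, 12.0: 38.0, 18.0: 57.0}

_STAGES = ("genotypes", "architecture", "weights", "fixed_effects")


@dataclass
class SimulationConfig:
    n_individuals: int = 808
    n_snps: int = 5000
    n_subpops: int = 5
    fst: float = 0.1
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_qtl: int = 20
    qtl_effect_matrix_mode: str = "pleiotropic"  # or "trait-specific"
    qtl_variance_share: float = 0.5              # genetic variance carried by QTL vs polygenic
    heritability_per_trait: tuple[float, float, float] = (0.4, 0.3, 0.3)
    param_means: tuple[float, float, float] = _PARAM_MEANS
    param_cvs: tuple[float, float, float] = _PARAM_CVS
    residual_weight_sd_by_age: dict = field(default_factory=lambda: dict(_RESID_SD))
    ages_months: tuple[float, ...] = (0.0, 6.0, 12.0, 18.0)
    fixed_effect_levels: dict = field(default_factory=lambda: {"breed": 3, "birth_year": 4, "birth_month": 6})
    fixed_effect_sds: dict = field(default_factory=lambda: {"breed": 10.0, "birth_year": 8.0, "birth_month": 5.0})
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        def bad(name, msg):
            raise ValueError(f"invalid SimulationConfig.{name}: {msg}")
        if self.n_individuals < 1:
            bad("n_individuals", "must be >= 1")
        if self.n_snps < 1:
            bad("n_snps", "must be >= 1")
        if self.n_subpops < 1:
            bad("n_subpops", "must be >= 1")
        lo, hi = self.maf_range
        if not (0 < lo <= hi <= 0.5):
            bad("maf_range", "must lie within (0, 0.5] with lo <= hi")
        if not 0 <= self.n_qtl <= self.n_snps:
            bad("n_qtl", "must satisfy 0 <= n_qtl <= n_snps")
        if self.qtl_effect_matrix_mode not in ("pleiotropic", "trait-specific"):
            bad("qtl_effect_matrix_mode", "must be 'pleiotropic' or 'trait-specific'")
        if not 0 <= self.qtl_variance_share <= 1:
            bad("qtl_variance_share", "must be in [0, 1]")
        if any(not (0 <= h < 1) for h in self.heritability_per_trait):
            bad("heritability_per_trait", "each must be in [0, 1)")
        if not 0 <= self.missing_rate <= 1:
            bad("missing_rate", "must be in [0, 1]")
        if not 0 <= self.fst < 1:
            bad("fst", "must be in [0, 1)")
        if len(self.ages_months) == 0:
            bad("ages_months", "must be non-empty")
        if self.param_means[0] <= 0 or self.param_means[2] <= 0:
            bad("param_means", "A and K means must be positive")

    def stage_rng(self, stage: str) -> np.random.Generator:
        """Deterministic child generator for one pipeline stage."""
        idx = _STAGES.index(stage)
        ss = np.random.SeedSequence(self.seed, spawn_key=(idx,))
        return np.random.default_rng(ss)


@dataclass
class TrueArchitecture:
    """Ground truth behind one simulated phenotype set."""

    qtl_indices: np.ndarray        # indices into the SNP columns
    qtl_effects: np.ndarray        # n_qtl x 3, additive effect per copy on (A, b, K)
    polygenic_values: np.ndarray   # n x 3
    genetic_values: np.ndarray     # n x 3 = QTL + polygenic
    true_params: np.ndarray        # n x 3 per-individual (A, b, K)


def simulate_genotypes(config: SimulationConfig) -> GenotypeMatrix:
    """Independent biallelic SNPs with Balding-Nichols subpopulation structure."""
    rng = config.stage_rng("genotypes")
    n, m = config.n_individuals, config.n_snps
    lo, hi = config.maf_range
    p_anc = rng.uniform(lo, hi, size=m)
    labels = rng.integers(0, config.n_subpops, size=n)
    F = config.fst
    if F > 0 and config.n_subpops > 1:
        a = p_anc * (1 - F) / F
        b = (1 - p_anc) * (1 - F) / F
        p_sub = rng.beta(a[None, :], b[None, :], size=(config.n_subpops, m))
        p_sub = np.clip(p_sub, 1e-6, 1 - 1e-6)
    else:
        p_sub = np.tile(p_anc, (config.n_subpops, 1))
    G = rng.binomial(2, p_sub[labels, :]).astype(float)
    if config.missing_rate > 0:
        G[rng.random(size=G.shape) < config.missing_rate] = np.nan
    snp_map = pd.DataFrame({
        "chrom": (np.arange(m) % 29) + 1,
        "pos": (np.arange(m) // 29 + 1) * 3000,   # ~3 kb spacing per chromosome
        "snp_id": [f"snp{j + 1}" for j in range(m)],
    })
    return GenotypeMatrix(matrix=G, snp_map=snp_map,
                          sample_ids=[f"ind{i + 1}" for i in range(n)],
                          subpop=labels)


def _rescale(values: np.ndarray, target_var: float) -> np.ndarray:
    """Scale a centered sample to an exact target variance (0 if target is 0)."""
    if target_var <= 0:
        return np.zeros_like(values)
    v = float(np.var(values, ddof=1)) if values.size > 1 else 0.0
    if v <= 0:
        return np.zeros_like(values)
    return values * np.sqrt(target_var / v)


def simulate_architecture(genotypes: GenotypeMatrix, config: SimulationConfig,
                          qtl_effects: np.ndarray | None = None,
                          qtl_indices: np.ndarray | None = None) -> TrueArchitecture:
    """Draw QTL effects, polygenic background and true (A, b, K) per animal.

    Each trait's total variance is (cv * mean)^2; the genetic share equals
    the configured heritability and is split between the sampled QTL and a
    polygenic term drawn with covariance proportional to the realised
    VanRaden kinship, so parameter phenotypes carry both detectable causal
    SNPs and a confounding genetic background.  Components are rescaled to
    their exact sample target variance, so realised heritabilities track
    the configuration closely.

    ``qtl_effects``/``qtl_indices`` override the random draw (useful to
    force effect signs in pleiotropy tests); effects are per B-allele copy
    before per-trait rescaling.
    """
    from .relatedness import vanraden_kinship

    rng = config.stage_rng("architecture")
    n = genotypes.n_individuals
    if config.n_qtl > genotypes.n_snps:
        raise ValueError("n_qtl exceeds the number of simulated SNPs")
    G = genotypes.imputed()
    means = np.asarray(config.param_means, dtype=float)
    total_var = (np.asarray(config.param_cvs, dtype=float) * means) ** 2
    h2 = np.asarray(config.heritability_per_trait, dtype=float)

    if qtl_indices is None:
        qtl_indices = np.sort(rng.choice(genotypes.n_snps, size=config.n_qtl, replace=False))
    else:
        qtl_indices = np.asarray(qtl_indices, dtype=int)
    n_qtl = len(qtl_indices)

    if qtl_effects is None:
        if config.qtl_effect_matrix_mode == "pleiotropic":
            qtl_effects = rng.standard_normal((n_qtl, 3))
        else:
            qtl_effects = np.zeros((n_qtl, 3))
            for i in range(n_qtl):
                qtl_effects[i, i % 3] = rng.standard_normal()
    else:
        qtl_effects = np.asarray(qtl_effects, dtype=float).reshape(n_qtl, 3)

    share = config.qtl_variance_share if n_qtl > 0 else 0.0
    qtl_raw = G[:, qtl_indices] @ qtl_effects if n_qtl > 0 else np.zeros((n, 3))

    poly_raw = np.zeros((n, 3))
    if h2.max() > 0 and share < 1.0:
        K = vanraden_kinship(genotypes)
        L = np.linalg.cholesky(K + 1e-6 * np.eye(n))
        poly_raw = L @ rng.standard_normal((n, 3))

    qtl_vals = np.zeros((n, 3))
    poly_vals = np.zeros((n, 3))
    realized_effects = qtl_effects.copy()
    for k in range(3):
        gv = h2[k] * total_var[k]
        qc = qtl_raw[:, k] - qtl_raw[:, k].mean()
        scaled = _rescale(qc, share * gv)
        # record the per-copy effect actually applied after rescaling
        if n_qtl > 0 and np.std(qtl_raw[:, k]) > 0 and share * gv > 0:
            realized_effects[:, k] = qtl_effects[:, k] * np.sqrt(
                share * gv / np.var(qc, ddof=1))
        elif n_qtl > 0:
            realized_effects[:, k] = 0.0
        qtl_vals[:, k] = scaled
        pc = poly_raw[:, k] - poly_raw[:, k].mean()
        poly_vals[:, k] = _rescale(pc, (1.0 - share) * gv)

    env = rng.standard_normal((n, 3)) * np.sqrt((1.0 - h2) * total_var)
    genetic = qtl_vals + poly_vals
    true_params = means + genetic + env

    # A and K must stay biologically positive; defaults leave ~7 SDs of room,
    # so clipping at a small positive floor only fires for extreme configs.
    true_params[:, 0] = np.maximum(true_params[:, 0], 1e-3 * means[0])
    true_params[:, 2] = np.maximum(true_params[:, 2], 1e-3 * means[2])

    return TrueArchitecture(qtl_indices=qtl_indices, qtl_effects=realized_effects,
                            polygenic_values=poly_vals, genetic_values=genetic,
                            true_params=true_params)


def simulate_weights(arch: TrueArchitecture, config: SimulationConfig,
                     max_retries: int = 20) -> pd.DataFrame:
    """Longitudinal weight records from the true Gompertz parameters.

    weight(i, t) = Gompertz(A_i, b_i, K_i, t) + fixed-effect offset_i
    + N(0, sd_t^2), one record per animal per age.  Fixed-effect levels
    (breed, birth year, birth month) are assigned uniformly; each level's
    additive shift is drawn once and applied at every age of the animal.
    Records whose noise draw makes the weight non-positive are resampled a
    bounded number of times before erroring.
    """
    rng = config.stage_rng("weights")
    fe_rng = config.stage_rng("fixed_effects")
    n = arch.true_params.shape[0]
    ages = np.asarray(config.ages_months, dtype=float)
    sd_map = {float(k): float(v) for k, v in config.residual_weight_sd_by_age.items()}

    levels = {}
    offsets = np.zeros(n)
    for factor, n_levels in config.fixed_effect_levels.items():
        lab = fe_rng.integers(0, max(int(n_levels), 1), size=n)
        eff = fe_rng.standard_normal(max(int(n_levels), 1)) * config.fixed_effect_sds.get(factor, 0.0)
        eff -= eff.mean()
        levels[factor] = lab
        offsets += eff[lab]

    rows = []
    for i in range(n):
        A, b, K = arch.true_params[i]
        for t in ages:
            base = predict_weight("gompertz", A, b, K, t) + offsets[i]
            sd = sd_map.get(float(t), 0.0)
            w = base + (rng.normal(0.0, sd) if sd > 0 else 0.0)
            tries = 0
            while w <= 0 and sd > 0 and tries < max_retries:
                w = base + rng.normal(0.0, sd)
                tries += 1
            if w <= 0:
                raise RuntimeError(
                    f"individual {i}: could not draw a positive weight at age {t}")
            rows.append({"id": f"ind{i + 1}", "age_months": t, "weight_kg": w,
                         "breed": f"B{levels['breed'][i] + 1}" if "breed" in levels else "B1",
                         "birth_year": f"Y{levels['birth_year'][i] + 1}" if "birth_year" in levels else "Y1",
                         "birth_month": f"M{levels['birth_month'][i] + 1}" if "birth_month" in levels else "M1"})
    return pd.DataFrame(rows)


def simulate_dataset(config: SimulationConfig):
    """One-call convenience: genotypes, architecture and weight records."""
    genos = simulate_genotypes(config)
    arch = simulate_architecture(genos, config)
    weights = simulate_weights(arch, config)
    return genos, arch, weights
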