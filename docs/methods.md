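# Methods

## Growth models and fitting

Each animal's weight–age series (W in kg, t in months, birth at t = 0) is
fitted by unweighted nonlinear least squares to one or more of

- Gompertz: W = A·exp(−b·e^(−Kt))
- Logistic: W = A·(1 + b·e^(−Kt))⁻¹
- Brody:   W = A·(1 − b·e^(−Kt))

with A > 0 the mature (asymptotic) weight in kg, b ≥ 0 dimensionless, K > 0
per month. The optimizer is Gauss–Newton with the analytic Jacobian of each
model; whenever a plain step would increase the RSS, Levenberg damping
(λ·diag(JᵀJ) added to the normal equations, λ escalated ×10 from 1e-4) is
engaged until the step descends. Convergence is declared when the relative
RSS change drops below 1e-10, capped at 100 iterations. Fits ending with
A ≤ 0 or K ≤ 0 are marked non-converged: the parameters are biologically
positive.

**Initialization.** Three parameters from as few as four observations make
the objective shallow, and for the Brody form the optimum asymptote can sit
several times above the largest observation. Starts are therefore generated
deterministically from a small ladder of candidate asymptotes (multiples of
max W: 1.05/1.2/1.5 for Gompertz and Logistic, 1.2–6.0 for Brody); each
candidate A₀ is log-linearised (e.g. ln ln(A₀/W) = ln b − Kt for Gompertz)
and regressed on t to give (b₀, K₀). All starts are polished and the
lowest-RSS converged fit is kept. This multi-start policy replaces a
single-start rule because the single start demonstrably stalls on the
Brody valley; it remains fully deterministic.

**Goodness of fit.** R² = 1 − SSE/SST per series. The population-level
comparison uses a pooled R²: all individuals' residuals jointly against the
grand-mean total sum of squares, giving one number per model; the model
with the highest pooled R² supplies the (A, b, K) phenotypes. Individuals
that fail to converge for the winning model are excluded from the phenotype
table and counted in the run report. R² is undefined (flagged) for a
constant observed series.

## Fixed-effect pre-adjustment

Weights are adjusted before curve fitting, one OLS model per age stratum,
on categorical breed, birth-year and birth-month factors (a Gaussian
identity-link GLM — the natural reading for a continuous response).
Adjusted weight = residual + stratum grand mean, which keeps the kg scale,
preserves stratum means, and is idempotent. Rank-deficient designs fall
back to the minimum-norm solution (aliased directions dropped, warned);
strata with no more records than estimable effects pass through unadjusted
with a warning. Fixed effects are handled here rather than inside the
growth model because they shift weights, not curve shape.

## Genotype QC, kinship, PCA

Filters run sequentially — duplicate (chrom, pos) first occurrence kept,
then missing-call fraction > 0.05 (i.e. call rate < 95%; the conventional
reading of a "call rate < 0.05" shorthand), then MAF < 0.01, then HWE
chi-square p < 1e-6 — and each SNP is counted once at its first failing
filter so the report reconciles exactly. HWE is the 1-df goodness-of-fit
chi-square against p², 2pq, q² expectations; monomorphic SNPs return p = 1
by convention (an exact-test oracle cross-checks accept/reject decisions in
the test suite only).

Kinship is VanRaden method 1, G = ZZᵀ / (2Σpₖ(1−pₖ)) on mean-imputed,
frequency-centered genotypes, zero-variance SNPs excluded from the scaling
sum; under HWE the diagonal averages ≈ 1. PCA takes the top eigenvectors of
the centered (optionally unit-scaled, default on) genotype matrix via SVD,
with a deterministic sign convention (largest-magnitude loading positive).
Three PCs are the default covariate set, overridable (`--pcs`), since the
appropriate count is data-dependent.

## Single-trait mixed model

Per trait y (one of Â, b̂, K̂): y = Ws + Xβ + u + e, u ~ N(0, Kσ²g),
e ~ N(0, Iσ²e), X = intercept + PCs (an intercept is always included for
identifiability). Variance components are estimated once under the no-SNP
model by REML: a single eigendecomposition of K rotates the model to
independent components, the restricted likelihood is profiled over
log(σ²g/σ²e) on a coarse grid over [−12, 12] refined by bounded Brent, and
edge estimates are flagged as boundary cases. The fitted ratio is then held
fixed for the scan (P3D/EMMAX); per-SNP exact REML is available behind
`exact_reml=True` for small data.

Each SNP is tested by weighted least squares in the rotated space with
weights 1/(λsᵢ+1), the residual scale re-estimated per SNP, t = ŝ/SE on
n − c − 1 degrees of freedom (c = covariate count including intercept).
This makes the scan *exactly* ordinary least squares when K = I. Missing
genotypes are mean-imputed so n is constant across SNPs; monomorphic or
covariate-collinear SNPs get NA rows with a reason rather than statistics.

The significance cutoff is the empirical FDR rule p\* = FDR × n/m with
n = #{p < 0.05} and m the SNP count. This equals the Benjamini–Hochberg
critical value evaluated at rank n, not the full step-up procedure: it is
monotone in n, collapses to the FDR level when every p < 0.05, and is kept
because it is the thresholding rule this pipeline is specified to use.

**Genetic correlation.** For a trait pair, both phenotypes are rotated into
the kinship eigenbasis and residualised on the covariates; the 2×2 genetic
and residual covariance matrices are then estimated by numerical maximum
likelihood (log-Cholesky parametrisation, Nelder–Mead from REML/moment
starts; each rotated pair is independent with covariance Σg·sᵢ + Σe).
r_g = σg12/√(σg1²σg2²), clamped to [−1, 1], undefined (flagged) when either
genetic variance hits the zero boundary. Pearson correlation of the raw
parameter estimates is available separately (`parameter_correlations`)
since reported parameter correlations may be either quantity.

## Multi-trait statistic

Per SNP, χ²_multi = tᵀV⁻¹t over the three single-trait t-values, p from
the 3-df chi-square upper tail. V is the Pearson correlation of the three
t-value vectors over "qualified" SNPs — all QC-passing SNPs with finite t
in every trait; an optional |t| cap (off by default) can exclude
strong-signal SNPs from V. t-values enter as-is rather than converted to
z: at several hundred residual degrees of freedom the difference is
negligible. V is floored at eigenvalue 1e-6 (with a warning, diagonal
re-normalised) when near-singular, e.g. duplicated traits.

## Synthetic data generator

The generator emulates the cohort design the pipeline targets: ~800 animals
weighed at 0/6/12/18 months, dense biallelic SNPs, visible population
stratification, and three genetically correlated curve parameters.

- **Genotypes.** Independent SNPs; ancestral frequency uniform in
  maf_range (default 0.05–0.5); subpopulation frequencies Balding–Nichols
  Beta draws at an Fst-like divergence (default 0.1 across 5
  subpopulations, enough for PCA to separate clusters); genotypes
  Binomial(2, p); optional uniform missingness.
- **Architecture.** n_qtl causal SNPs (default 20, pleiotropic mode: one
  effect per trait per QTL) plus a polygenic term drawn with covariance
  proportional to the realized VanRaden kinship. Per trait, total variance
  is (cv·mean)²; the genetic share equals the configured heritability
  (defaults 0.4/0.3/0.3) and is split QTL/polygenic by qtl_variance_share
  (default 0.5). Components are rescaled to exact sample target variances,
  so realized heritabilities track the configuration.
- **Weights.** Gompertz forward evaluation at the true (A, b, K), plus a
  per-animal fixed-effect offset (breed/year/month levels, additive,
  common to all ages — they shift weight, not curve shape), plus
  age-specific Gaussian noise; non-positive draws are resampled a bounded
  number of times. All stages draw from deterministic children of one
  master seed.

**Calibration.** Parameter means default to the fitted cohort curve
(617.9 kg, 2.74, 0.153/mo). CVs (0.08, 0.04, 0.08) and per-age residual
SDs {0: 3, 6: 30, 12: 38, 18: 57} kg were set once by first-order error
propagation so the per-age weight SDs aggregate to ≈ 6.2/39.5/56.2/73.2 kg;
the within-animal residual variance is not observable from published
summaries, so this split is a modelling choice (the age-0 SD pins it from
below, the later ages from above). Realized SDs run a few percent low at
12–18 months because pleiotropy induces a negative A–K genetic correlation
that propagation ignores.

**What it does not emulate** (hence what green tests do not show about real
data): linkage disequilibrium and local association peaks, genotyping
error, pedigree/family structure beyond the subpopulation model,
heterogeneous residuals between animals, selection, and age-dependent
fixed effects.

## Problem sizes in the checks

The calibration and recovery checks use simulations sized to make their
tolerances meaningful while staying desk-scale: 500×2000 for single-trait
type-I error (binomial 3-SE band ±0.015), 20 replicates of 200×600 for the
3-df null calibration (KS at α = 0.01), n = 500 with 20 replicates for
heritability (±0.15) and genetic correlation (±0.2) recovery, and a
200×1000 end-to-end smoke run. Null-calibration simulations place the
polygenic background on a marker set disjoint from the tested SNPs;
otherwise every tested SNP carries a small real effect (non-centrality
≈ n·h²/m) and the median statistic is genuinely, if mildly, inflated —
a property of the design, not a miscalibration.

## Known limitations

- **Mature weight from four observations is noisy.** With the calibrated
  residual SDs, the sampling error of Â per animal is large (the recovery
  test quantifies a median relative error on the order of 10–15%): A hangs
  almost entirely on the single 18-month record, and no estimator can do
  better from the same four points. Population-level inference (GWAS on
  many animals) tolerates this as phenotype measurement error; per-animal
  asymptote predictions should not be trusted at this observation density.
- The compressed mixed model (grouping animals by kinship before fitting)
  is not implemented; the scan is plain MLM with P3D.
- The FDR rule is the empirical n/m cutoff described above, not full BH.
- Brody fits report the least-squares optimum even when the asymptote is
  biologically implausible; model choice by pooled R² is the guard.
- The annotator is purely positional (nearest edge, ties reported both
  ways, BED half-open converted to 1-based closed); no transcript-aware
  consequence prediction.
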