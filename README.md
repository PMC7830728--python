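# growthgwas

GWAS of growth-curve parameters from longitudinal body weights.

Beef-cattle breeding programs weigh animals a handful of times (here at 0,
6, 12 and 18 months) and want the genetics of the whole growth trajectory,
not of any single weighing. `growthgwas` condenses each animal's
weight–age series into the three parameters of a nonlinear growth model
and then maps the loci that shape them:

1. **Pre-adjustment** — weights at each age are adjusted for breed, birth
   year and birth month by an OLS model on categorical factors.
2. **Growth-curve fitting** — per animal, Gauss–Newton least squares for
   three classical models (W in kg, t in months):

   | model    | function                  |
   |----------|---------------------------|
   | Gompertz | W = A·exp(−b·e^(−Kt))     |
   | Logistic | W = A·(1 + b·e^(−Kt))⁻¹   |
   | Brody    | W = A·(1 − b·e^(−Kt))     |

   A is the mature body weight (kg), b the dimensionless time-scale
   parameter, K the maturity rate (1/month). The model with the highest
   pooled R² wins, and its per-animal (A, b, K) become the phenotypes.
3. **Single-trait GWAS** — mixed linear model per SNP,
   y = Ws + Xβ + u + e with u ~ N(0, Kσ²g), kinship K by VanRaden method 1,
   covariates = intercept + leading genotype PCs, variance components by
   REML once under the no-SNP model (P3D/EMMAX scheme).
4. **Multi-trait GWAS** — per SNP the t-values of the three traits are
   combined into χ² = tᵀV⁻¹t with V the between-trait t-value correlation
   over qualified SNPs; 3-df chi-square p-values flag pleiotropic loci.
5. **FDR threshold** — empirical cutoff p\* = FDR × #{p < 0.05}/m.
6. **Annotation** — nearest gene per significant SNP from a local BED file.

A fully seeded synthetic-data module (structured genotypes, pleiotropic
QTL, kinship-structured polygenic background, age-specific weight noise)
makes every stage testable against known ground truth.

## Worked example

Fitting the three models to a cohort's mean weights (kg) at 0/6/12/18
months:

```python
from growthgwas import fit_curve

ages = [0, 6, 12, 18]                       # months
weights = [38.79, 208.68, 398.70, 520.10]   # cohort mean weights, kg
for model in ("gompertz", "logistic", "brody"):
    fit = fit_curve(ages, weights, model=model)
    print(f"{model:9s} A={fit.A:8.1f} kg  b={fit.b:6.3f}  K={fit.K:6.3f}/mo  "
          f"R2={fit.r_squared:.4f}")
```

```
gompertz  A=   617.9 kg  b= 2.740  K= 0.153/mo  R2=1.0000
logistic  A=   551.0 kg  b= 9.304  K= 0.273/mo  R2=0.9965
brody     A=  1458.5 kg  b= 0.976  K= 0.023/mo  R2=0.9968
```

The Gompertz asymptote (618 kg) sits inside the plausible mature-weight
range for a large beef breed; the Brody asymptote (1459 kg) illustrates
how weakly A is identified when the series ends far from the plateau.

An end-to-end run on simulated data (also available as
`growthgwas run-all --n 200 --snps 1000 --seed 1`):

```python
from growthgwas.pipeline import RunConfig, run_pipeline
from growthgwas.simulate import SimulationConfig

cfg = RunConfig(out_dir="demo", seed=1,
                sim=SimulationConfig(n_individuals=200, n_snps=1000, n_qtl=10, seed=1))
report = run_pipeline(cfg)
```

prints a reconciled run report whose key numbers for this seed are:

```
selected model: gompertz
pooled R2: {'gompertz': 0.9959, 'logistic': 0.9947, 'brody': 0.9888}
single-trait significant SNPs: {'A': 8, 'b': 3, 'K': 4}
multi-trait significant SNPs: 7
```

i.e. the generating model is recovered, and at a 5% empirical FDR the
scans flag a handful of loci — the simulation planted 10 pleiotropic QTL.
All stage outputs (filtered PED/MAP, kinship, PCs, per-trait association
TSVs, Manhattan/QQ data files, annotation) land in `demo/` with checksums
in `demo/run_report.json`.

## Layout

- `src/growthgwas/` — library (`simulate`, `preadjust`, `growth`, `qc`,
  `relatedness`, `mlm`, `multitrait`, `annotate`, `pipeline`, `cli`)
- `tests/` — unit, property and acceptance tests
- `docs/methods.md` — models, assumptions, calibration and numerical notes
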