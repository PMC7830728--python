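"""End-to-end orchestration: simulate -> QC -> pre-adjust -> fit -> GWAS -> annotate.

Each stage writes its outputs before the next starts, all files land in the
run's output directory, and the machine-readable run report reconciles
counts (QC totals, converged fits, significant SNPs) and lists every output
with a checksum.  Rerunning with the same config and seed reproduces
byte-identical outputs.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd

from . import io as gio
from .annotate import annotate_snps, read_bed_genes
from .growth import MODELS, fit_population, parameter_correlations
from .mlm import fdr_threshold, snp_scan
from .multitrait import MultiTraitScan
from .preadjust import adjust_weights
from .qc import apply_qc
from .relatedness import pca, vanraden_kinship
from .simulate import SimulationConfig, simulate_dataset

log = logging.getLogger("growthgwas")

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    out_dir: str = "run"
    # inputs; when absent, data are simulated with `sim`
    ped_prefix: str | None = None
    phenotype_file: str | None = None
    gene_bed: str | None = None
    simulate: bool = True
    sim: SimulationConfig = field(default_factory=SimulationConfig)
    # analysis settings (PLINK-style QC defaults; 3 PCs; 5% FDR)
    maf: float = 0.01
    missing: float = 0.05
    hwe_p: float = 1e-6
    n_pcs: int = 3
    fdr_level: float = 0.05
    models: tuple = MODELS
    max_gene_distance: int = 1_000_000
    seed: int = 0

    def validate(self):
        if not 0 <= self.maf <= 0.5 or not 0 <= self.missing <= 1 or not 0 <= self.hwe_p <= 1:
            raise ValueError("QC thresholds out of range")
        if not 0 < self.fdr_level < 1:
            raise ValueError("fdr_level must be in (0, 1)")
        if self.n_pcs < 0:
            raise ValueError("n_pcs must be >= 0")
        for path in (self.ped_prefix and Path(self.ped_prefix).with_suffix(".ped"),
                     self.phenotype_file and Path(self.phenotype_file),
                     self.gene_bed and Path(self.gene_bed)):
            if path is not None and not Path(path).exists():
                raise FileNotFoundError(f"configured input does not exist: {path}")
        if not self.simulate and (self.ped_prefix is None or self.phenotype_file is None):
            raise ValueError("without simulation both ped_prefix and phenotype_file are required")


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig) -> dict:
    """Execute all stages in order; returns (and writes) the run report."""
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report: dict = {"stages": [], "settings": {
        "maf": config.maf, "missing": config.missing, "hwe_p": config.hwe_p,
        "n_pcs": config.n_pcs, "fdr_level": config.fdr_level,
        "models": list(config.models), "seed": config.seed,
    }}
    manifest: list[Path] = []

    def done(stage, **info):
        log.info("stage %s done: %s", stage, info)
        report["stages"].append({"name": stage, **info})

    # --- inputs -----------------------------------------------------------
    if config.simulate:
        sim = SimulationConfig(**{**asdict(config.sim), "seed": config.seed})
        genos, arch, records = simulate_dataset(sim)
        gio.write_ped_map(genos, out / "genotypes")
        gio.write_phenotypes(records, out / "phenotypes.tsv")
        gio.write_truth(arch, genos, out / "truth.tsv")
        manifest += [out / "genotypes.ped", out / "genotypes.map",
                     out / "phenotypes.tsv", out / "truth.tsv"]
        done("simulate", n_individuals=genos.n_individuals, n_snps=genos.n_snps,
             n_qtl=len(arch.qtl_indices))
    else:
        genos = gio.read_ped_map(config.ped_prefix)
        records = gio.read_phenotypes(config.phenotype_file)
        done("load", n_individuals=genos.n_individuals, n_snps=genos.n_snps,
             n_records=len(records))

    # --- QC + structure ---------------------------------------------------
    genos_qc, qc_report = apply_qc(genos, maf=config.maf, missing=config.missing,
                                   hwe_p=config.hwe_p)
    if not qc_report.reconciles():
        raise RuntimeError("QC report does not reconcile")
    qc_df = pd.DataFrame([qc_report.__dict__])
    qc_df.to_csv(out / "qc_report.tsv", sep="\t", index=False)
    gio.write_ped_map(genos_qc, out / "genotypes_qc")
    manifest += [out / "qc_report.tsv", out / "genotypes_qc.ped", out / "genotypes_qc.map"]
    done("qc", **{k: v for k, v in qc_report.__dict__.items() if k.startswith("n_")})

    K = vanraden_kinship(genos_qc)
    kin_df = pd.DataFrame(K, index=genos_qc.sample_ids, columns=genos_qc.sample_ids)
    kin_df.to_csv(out / "kinship.tsv", sep="\t")
    pcs_df, evr = (None, None)
    if config.n_pcs > 0:
        pcs_df, evr = pca(genos_qc, n_components=config.n_pcs)
        pcs_df.to_csv(out / "pcs.tsv", sep="\t", index=False)
        manifest.append(out / "pcs.tsv")
    manifest.append(out / "kinship.tsv")
    done("structure", n_pcs=config.n_pcs,
         explained_variance=[float(x) for x in (evr if evr is not None else [])])

    # --- pre-adjustment and curve fitting ---------------------------------
    adjusted, effects = adjust_weights(records)
    gio.write_phenotypes(adjusted, out / "phenotypes_adjusted.tsv")
    effects.to_csv(out / "fixed_effects.tsv", sep="\t", index=False)
    manifest += [out / "phenotypes_adjusted.tsv", out / "fixed_effects.tsv"]
    done("adjust", n_records=len(adjusted))

    pop = fit_population(adjusted, models=config.models)
    pop.fits.to_csv(out / "curve_fits.tsv", sep="\t", index=False)
    pd.DataFrame([{"model": m, "pooled_r2": r} for m, r in pop.pooled_r2.items()]
                 ).to_csv(out / "model_comparison.tsv", sep="\t", index=False)
    pop.phenotypes.to_csv(out / "growth_parameters.tsv", sep="\t", index=False)
    corr = parameter_correlations(pop.phenotypes)
    corr.to_csv(out / "parameter_correlations.tsv", sep="\t")
    manifest += [out / "curve_fits.tsv", out / "model_comparison.tsv",
                 out / "growth_parameters.tsv", out / "parameter_correlations.tsv"]
    done("fit", selected_model=pop.selected_model,
         pooled_r2=pop.pooled_r2, n_phenotyped=len(pop.phenotypes),
         n_failed=pop.n_failed)

    # --- single-trait GWAS ------------------------------------------------
    # align genotype rows to phenotyped individuals
    idx = {sid: i for i, sid in enumerate(genos_qc.sample_ids)}
    keep = [idx[i] for i in pop.phenotypes["id"] if i in idx]
    pheno = pop.phenotypes[pop.phenotypes["id"].isin(idx)].reset_index(drop=True)
    Gm = genos_qc.matrix[keep]
    Ksub = K[np.ix_(keep, keep)]
    covs = pcs_df.iloc[keep, 1:].to_numpy(dtype=float) if pcs_df is not None else None
    from .genotypes import GenotypeMatrix
    genos_sub = GenotypeMatrix(matrix=Gm, snp_map=genos_qc.snp_map,
                               sample_ids=list(pheno["id"]))

    single = {}
    sig_counts = {}
    for trait in ("A", "b", "K"):
        res = snp_scan(genos_sub, pheno[trait].to_numpy(dtype=float),
                       covariates=covs, kinship=Ksub)
        thr, passes = fdr_threshold(res["p"], config.fdr_level)
        res.to_csv(out / f"gwas_{trait}.tsv", sep="\t", index=False)
        plot = res[["chrom", "pos"]].copy()
        with np.errstate(divide="ignore"):
            plot["neglog10p"] = -np.log10(res["p"])
        plot.to_csv(out / f"manhattan_{trait}.tsv", sep="\t", index=False)
        manifest += [out / f"gwas_{trait}.tsv", out / f"manhattan_{trait}.tsv"]
        single[trait] = res
        sig_counts[trait] = int(passes.sum())
        done(f"gwas_{trait}", p_threshold=thr.p_threshold, n_significant=int(passes.sum()),
             heritability=None)
    report["single_trait_significant"] = sig_counts

    # --- multi-trait GWAS -------------------------------------------------
    mt = MultiTraitScan(fdr_level=config.fdr_level).fit(single)
    mt.results_.to_csv(out / "gwas_multitrait.tsv", sep="\t", index=False)
    pd.DataFrame(mt.trait_correlation_.V, index=["A", "b", "K"], columns=["A", "b", "K"]
                 ).to_csv(out / "trait_correlation.tsv", sep="\t")
    manifest += [out / "gwas_multitrait.tsv", out / "trait_correlation.tsv"]
    done("multitrait", p_threshold=mt.threshold_.p_threshold,
         n_significant=len(mt.significant_))
    report["multitrait_significant"] = len(mt.significant_)

    # --- annotation -------------------------------------------------------
    if config.gene_bed is not None:
        genes = read_bed_genes(config.gene_bed)
        sig_all = []
        for trait, res in single.items():
            thr, passes = fdr_threshold(res["p"], config.fdr_level)
            sub = res[passes].copy()
            sub["trait"] = trait
            sig_all.append(sub)
        sig_all.append(mt.significant_.assign(trait="multi"))
        sig_df = pd.concat(sig_all, ignore_index=True)
        if len(sig_df):
            ann = annotate_snps(sig_df, genes, max_distance=config.max_gene_distance)
        else:
            ann = pd.DataFrame(columns=["snp_id", "chrom", "pos", "p",
                                        "distance", "relation", "side", "gene"])
        ann.to_csv(out / "annotation.tsv", sep="\t", index=False)
        manifest.append(out / "annotation.tsv")
        done("annotate", n_annotated=len(ann))

    report["manifest"] = {str(p.relative_to(out)): _sha256(p) for p in manifest}
    (out / "run_report.json").write_text(json.dumps(report, indent=2, default=str))
    return report
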