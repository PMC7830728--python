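"""Text-format readers and writers: PLINK PED/MAP, long-format phenotypes, truth files.

Genotypes travel as PLINK text PED/MAP with alleles written A/B (missing
"0 0"), additive coding counting B copies; phenotypes as a tab-separated
long table (id, age_months, weight_kg, breed, birth_year, birth_month).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .genotypes import GenotypeMatrix

__all__ = ["write_ped_map", "read_ped_map", "write_phenotypes", "read_phenotypes",
           "write_truth", "read_truth", "load_config", "dump_config"]

_ALLELES = {0.0: "A A", 1.0: "A B", 2.0: "B B"}

PHENO_COLUMNS = ["id", "age_months", "weight_kg", "breed", "birth_year", "birth_month"]


def write_ped_map(genotypes: GenotypeMatrix, prefix) -> tuple[Path, Path]:
    """Write <prefix>.ped and <prefix>.map (PLINK text)."""
    prefix = Path(prefix)
    ped_path = prefix.with_suffix(".ped")
    map_path = prefix.with_suffix(".map")
    with open(map_path, "w") as fh:
        for _, row in genotypes.snp_map.iterrows():
            fh.write(f"{row['chrom']}\t{row['snp_id']}\t0\t{row['pos']}\n")
    with open(ped_path, "w") as fh:
        for i, sid in enumerate(genotypes.sample_ids):
            geno = " ".join(
                _ALLELES.get(g, "0 0") if not np.isnan(g) else "0 0"
                for g in genotypes.matrix[i]
            )
            fh.write(f"FAM1 {sid} 0 0 0 -9 {geno}\n")
    return ped_path, map_path


def read_ped_map(prefix) -> GenotypeMatrix:
    """Read PLINK text PED/MAP into additive coding (count of B alleles).

    For each SNP the B allele is the lexicographically larger of the two
    alleles observed at that marker (so files written by
    :func:`write_ped_map` round-trip exactly); monomorphic markers count
    copies of the single observed allele as 0.
    """
    prefix = Path(prefix)
    snp_map = pd.read_csv(prefix.with_suffix(".map"), sep=r"\s+", header=None,
                          names=["chrom", "snp_id", "cm", "pos"])
    m = len(snp_map)
    sample_ids = []
    raw = []
    with open(prefix.with_suffix(".ped")) as fh:
        for line in fh:
            parts = line.split()
            if not parts:
                continue
            if len(parts) != 6 + 2 * m:
                raise ValueError(f"PED line for {parts[1] if len(parts) > 1 else '?'} "
                                 f"has {len(parts) - 6} allele fields; expected {2 * m}")
            sample_ids.append(parts[1])
            raw.append(parts[6:])
    alleles = np.array(raw, dtype="U2").reshape(len(raw), m, 2)
    G = np.full((len(raw), m), np.nan)
    for j in range(m):
        col = alleles[:, j, :]
        obs = sorted(set(col.ravel()) - {"0"})
        if not obs:
            continue
        b_allele = obs[-1]
        missing = np.any(col == "0", axis=1)
        G[:, j] = np.sum(col == b_allele, axis=1).astype(float)
        G[missing, j] = np.nan
    return GenotypeMatrix(matrix=G, snp_map=snp_map[["chrom", "pos", "snp_id"]],
                          sample_ids=sample_ids)


def write_phenotypes(records: pd.DataFrame, path) -> Path:
    path = Path(path)
    records[PHENO_COLUMNS].to_csv(path, sep="\t", index=False)
    return path


def read_phenotypes(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PHENO_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"phenotype file lacks columns: {missing}")
    return df


def write_truth(arch, genotypes: GenotypeMatrix, path) -> Path:
    """Ground-truth table (id, A, b, K) plus the causal SNP ids as a header line."""
    path = Path(path)
    qtl_ids = [genotypes.snp_map["snp_id"].iloc[j] for j in arch.qtl_indices]
    with open(path, "w") as fh:
        fh.write("# qtl: " + ",".join(qtl_ids) + "\n")
        truth = pd.DataFrame(arch.true_params, columns=["A", "b", "K"])
        truth.insert(0, "id", genotypes.sample_ids)
        truth.to_csv(fh, sep="\t", index=False)
    return path


def read_truth(path) -> tuple[pd.DataFrame, list[str]]:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        qtl = header.removeprefix("# qtl:").strip().split(",") if header.startswith("# qtl:") else []
        df = pd.read_csv(fh, sep="\t")
    return df, [q for q in qtl if q]


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    return cfg or {}


def dump_config(cfg: dict, path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(cfg, fh, sort_keys=True)
    return path
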