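"""Additive-coded genotype container shared by the simulation, QC and GWAS stages."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["GenotypeMatrix"]


@dataclass
class GenotypeMatrix:
    """n individuals x m SNPs, entries {0, 1, 2, NaN} counting B alleles.

    ``snp_map`` carries one row per SNP with columns ``chrom``, ``pos`` (bp)
    and ``snp_id``; ``subpop`` optionally records simulated subpopulation
    labels for structure-aware tests.
    """

    matrix: np.ndarray
    snp_map: pd.DataFrame
    sample_ids: list = field(default_factory=list)
    subpop: np.ndarray | None = None

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, dtype=float)
        if self.matrix.ndim != 2:
            raise ValueError("genotype matrix must be 2-D (individuals x SNPs)")
        if len(self.snp_map) != self.matrix.shape[1]:
            raise ValueError("snp_map length must equal the number of SNP columns")
        if not self.sample_ids:
            self.sample_ids = [f"ind{i + 1}" for i in range(self.matrix.shape[0])]
        if len(self.sample_ids) != self.matrix.shape[0]:
            raise ValueError("sample_ids length must equal the number of rows")
        if (self.snp_map["pos"] < 0).any():
            raise ValueError("SNP positions must be non-negative")

    @property
    def n_individuals(self) -> int:
        return self.matrix.shape[0]

    @property
    def n_snps(self) -> int:
        return self.matrix.shape[1]

    def imputed(self) -> np.ndarray:
        """Copy with missing entries replaced by the per-SNP mean."""
        G = self.matrix.copy()
        means = np.nanmean(np.where(np.isnan(G), np.nan, G), axis=0)
        means = np.where(np.isnan(means), 0.0, means)  # all-missing column
        idx = np.where(np.isnan(G))
        G[idx] = means[idx[1]]
        return G

    def subset_snps(self, keep: np.ndarray) -> "GenotypeMatrix":
        return GenotypeMatrix(
            matrix=self.matrix[:, keep],
            snp_map=self.snp_map.iloc[keep].reset_index(drop=True),
            sample_ids=list(self.sample_ids),
            subpop=self.subpop,
        )
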