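"""Per-SNP quality control: duplicates, call rate, minor allele frequency, HWE.

Filters are applied sequentially (duplicates -> call rate -> MAF -> HWE) so
each removed SNP is counted exactly once, at the first filter it fails; the
report reconciles counts against the input.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, TransformerMixin

from .genotypes import GenotypeMatrix

__all__ = ["QCReport", "compute_maf", "hwe_test", "GenotypeQC", "apply_qc"]


@dataclass
class QCReport:
    n_input: int
    n_removed_duplicate: int
    n_removed_callrate: int
    n_removed_maf: int
    n_removed_hwe: int
    n_retained: int
    maf_threshold: float
    callrate_missing_threshold: float
    hwe_p_threshold: float

    def reconciles(self) -> bool:
        removed = (self.n_removed_duplicate + self.n_removed_callrate
                   + self.n_removed_maf + self.n_removed_hwe)
        return self.n_input == removed + self.n_retained


def compute_maf(column) -> float:
    """Minor allele frequency of one SNP column ({0,1,2,NaN} coding).

    min(p, 1-p) with p the B-allele frequency over non-missing calls.
    """
    g = np.asarray(column, dtype=float)
    ok = ~np.isnan(g)
    n = int(ok.sum())
    if n == 0:
        raise ValueError("all calls missing: MAF undefined")
    p = float(g[ok].sum()) / (2 * n)
    return min(p, 1.0 - p)


def hwe_test(column) -> float:
    """1-df chi-square Hardy-Weinberg goodness-of-fit p-value.

    Observed genotype counts are compared with the p^2 / 2pq / q^2
    expectations at the sample allele frequency.  A monomorphic SNP has no
    testable departure and returns p = 1 by convention.
    """
    g = np.asarray(column, dtype=float)
    g = g[~np.isnan(g)]
    n = g.size
    if n == 0:
        raise ValueError("all calls missing: HWE undefined")
    n0 = int(np.sum(g == 0))
    n1 = int(np.sum(g == 1))
    n2 = int(np.sum(g == 2))
    p = (2 * n2 + n1) / (2 * n)
    q = 1.0 - p
    if p == 0.0 or q == 0.0:
        return 1.0
    expected = np.array([q * q, 2 * p * q, p * p]) * n
    observed = np.array([n0, n1, n2], dtype=float)
    chi2 = float(np.sum((observed - expected) ** 2 / expected))
    return float(stats.chi2.sf(chi2, df=1))


class GenotypeQC(TransformerMixin, BaseEstimator):
    """SNP filter with PLINK-style thresholds.

    Parameters
    ----------
    maf : float
        Remove SNPs with minor allele frequency below this (default 0.01).
    missing : float
        Remove SNPs with missing-call fraction above this (default 0.05,
        i.e. call rate below 95%).
    hwe_p : float
        Remove SNPs with HWE chi-square p below this (default 1e-6).

    ``fit`` computes the keep mask and report; ``transform`` returns the
    filtered :class:`GenotypeMatrix`.
    """

    def __init__(self, maf: float = 0.01, missing: float = 0.05, hwe_p: float = 1e-6):
        self.maf = maf
        self.missing = missing
        self.hwe_p = hwe_p

    def fit(self, X: GenotypeMatrix, y=None):
        if not (0 <= self.maf <= 0.5 and 0 <= self.missing <= 1 and 0 <= self.hwe_p <= 1):
            raise ValueError("QC thresholds out of range")
        G = X.matrix
        m = X.n_snps
        removed = np.zeros(m, dtype=int)  # 0 keep, 1 dup, 2 callrate, 3 maf, 4 hwe

        dup = X.snp_map.duplicated(subset=["chrom", "pos"], keep="first").to_numpy()
        removed[dup] = 1

        miss_frac = np.isnan(G).mean(axis=0)
        cand = removed == 0
        removed[cand & (miss_frac > self.missing)] = 2

        cand = removed == 0
        for j in np.where(cand)[0]:
            try:
                if compute_maf(G[:, j]) < self.maf:
                    removed[j] = 3
            except ValueError:
                removed[j] = 2  # all-missing fails call rate regardless
        cand = removed == 0
        for j in np.where(cand)[0]:
            if hwe_test(G[:, j]) < self.hwe_p:
                removed[j] = 4

        self.keep_mask_ = removed == 0
        self.report_ = QCReport(
            n_input=m,
            n_removed_duplicate=int(np.sum(removed == 1)),
            n_removed_callrate=int(np.sum(removed == 2)),
            n_removed_maf=int(np.sum(removed == 3)),
            n_removed_hwe=int(np.sum(removed == 4)),
            n_retained=int(self.keep_mask_.sum()),
            maf_threshold=self.maf,
            callrate_missing_threshold=self.missing,
            hwe_p_threshold=self.hwe_p,
        )
        return self

    def transform(self, X: GenotypeMatrix) -> GenotypeMatrix:
        if self.report_.n_retained == 0:
            raise RuntimeError("QC removed every SNP; pipeline halted")
        return X.subset_snps(np.where(self.keep_mask_)[0])


def apply_qc(genotypes: GenotypeMatrix, maf: float = 0.01, missing: float = 0.05,
             hwe_p: float = 1e-6) -> tuple[GenotypeMatrix, QCReport]:
    qc = GenotypeQC(maf=maf, missing=missing, hwe_p=hwe_p).fit(genotypes)
    return qc.transform(genotypes), qc.report_
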