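"""Multi-trait chi-square pleiotropy scan.

For each SNP the three single-trait t-values (for the growth parameters
A, b, K) are combined into the quadratic form

    chi2_multi = t' V^{-1} t

where V is the 3x3 Pearson correlation matrix of the t-value vectors over
the qualified SNPs (all QC-passing SNPs with a finite t in every trait).
Under the null the statistic follows a chi-square distribution with 3
degrees of freedom; correlated traits therefore cost no extra tests while
shared signal accumulates across traits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .mlm import FdrThreshold, fdr_threshold

__all__ = ["TraitCorrelation", "estimate_trait_correlation",
           "multitrait_statistic", "MultiTraitScan", "multitrait_scan"]

TRAITS = ("A", "b", "K")


@dataclass
class TraitCorrelation:
    """Between-trait t-value correlation with a cached stabilised inverse."""

    V: np.ndarray
    V_inv: np.ndarray
    n_qualified: int
    floored: bool    # eigenvalue flooring engaged to restore positive definiteness


def _align(tables: dict[str, pd.DataFrame]) -> pd.DataFrame:
    """One row per SNP with t_A, t_b, t_K; rejects misaligned SNP sets."""
    ids = [tuple(tab["snp_id"]) for tab in tables.values()]
    if len(set(ids)) != 1:
        sets = [set(i) for i in ids]
        offending = sorted(set.union(*sets) - set.intersection(*sets))[:10]
        raise ValueError(f"single-trait tables cover different SNP sets "
                         f"(e.g. {offending}) or orders differ")
    first = next(iter(tables.values()))
    out = first[["snp_id", "chrom", "pos"]].copy()
    for trait in TRAITS:
        out[f"t_{trait}"] = tables[trait]["t"].to_numpy(dtype=float)
    return out


def estimate_trait_correlation(single_trait_results: dict[str, pd.DataFrame],
                               max_abs_t: float | None = None) -> TraitCorrelation:
    """Pearson correlation of the three t-value vectors over qualified SNPs.

    Qualified = finite t in all three traits; ``max_abs_t`` optionally
    excludes strong-signal SNPs (|t| above the cut in any trait) so large
    causal effects do not contaminate the null correlation.  Positive
    definiteness is enforced by flooring eigenvalues at 1e-6 (warned).
    """
    aligned = _align(single_trait_results)
    T = aligned[[f"t_{tr}" for tr in TRAITS]].to_numpy(dtype=float)
    ok = np.all(np.isfinite(T), axis=1)
    if max_abs_t is not None:
        ok &= np.all(np.abs(T) < max_abs_t, axis=1)
    T = T[ok]
    if T.shape[0] < 2:
        raise ValueError("fewer than 2 qualified SNPs: correlation inestimable")
    with np.errstate(invalid="ignore"):
        V = np.corrcoef(T, rowvar=False)
    V = np.where(np.isfinite(V), V, 0.0)
    np.fill_diagonal(V, 1.0)
    vals, vecs = np.linalg.eigh((V + V.T) / 2.0)
    floored = bool(vals.min() < 1e-6)
    if floored:
        warnings.warn(f"trait t-value correlation near-singular "
                      f"(min eigenvalue {vals.min():.3g}); flooring at 1e-6")
        vals = np.maximum(vals, 1e-6)
        V = vecs @ np.diag(vals) @ vecs.T
        d = np.sqrt(np.diag(V))
        V = V / np.outer(d, d)
        vals, vecs = np.linalg.eigh((V + V.T) / 2.0)
        vals = np.maximum(vals, 1e-6)
    V_inv = vecs @ np.diag(1.0 / vals) @ vecs.T
    return TraitCorrelation(V=V, V_inv=V_inv, n_qualified=int(T.shape[0]),
                            floored=floored)


def multitrait_statistic(t, corr: TraitCorrelation):
    """chi2 = t' V^{-1} t and its 3-df upper-tail p for one SNP's t-triple.

    A non-finite entry in ``t`` yields (NaN, NaN).
    """
    t = np.asarray(t, dtype=float).reshape(-1)
    if t.size != 3:
        raise ValueError("expected a 3-vector of t-values")
    if not np.all(np.isfinite(t)):
        return float("nan"), float("nan")
    chi2 = float(t @ corr.V_inv @ t)
    return chi2, float(stats.chi2.sf(chi2, df=3))


class MultiTraitScan(BaseEstimator):
    """Whole-genome pleiotropy scan over aligned single-trait results.

    ``fit({'A': tab, 'b': tab, 'K': tab})`` populates ``results_`` (snp_id,
    chrom, pos, chi2, p, note), ``trait_correlation_`` and, at the given
    ``fdr_level``, ``threshold_`` / ``significant_``.
    """

    def __init__(self, fdr_level: float = 0.05, max_abs_t: float | None = None):
        self.fdr_level = fdr_level
        self.max_abs_t = max_abs_t

    def fit(self, single_trait_results: dict[str, pd.DataFrame], y=None):
        corr = estimate_trait_correlation(single_trait_results, max_abs_t=self.max_abs_t)
        aligned = _align(single_trait_results)
        T = aligned[[f"t_{tr}" for tr in TRAITS]].to_numpy(dtype=float)
        finite = np.all(np.isfinite(T), axis=1)
        Tz = np.where(finite[:, None], T, 0.0)
        chi2 = np.einsum("ij,jk,ik->i", Tz, corr.V_inv, Tz)
        chi2[~finite] = np.nan
        p = stats.chi2.sf(chi2, df=3)
        self.trait_correlation_ = corr
        self.results_ = pd.DataFrame({
            "snp_id": aligned["snp_id"], "chrom": aligned["chrom"],
            "pos": aligned["pos"], "chi2": chi2, "p": p,
            "note": np.where(finite, "", "missing_t"),
        })
        self.threshold_, passes = fdr_threshold(p, self.fdr_level)
        self.significant_ = self.results_[passes].reset_index(drop=True)
        return self


def multitrait_scan(single_trait_results: dict[str, pd.DataFrame],
                    fdr_level: float = 0.05,
                    max_abs_t: float | None = None) -> tuple[pd.DataFrame, FdrThreshold]:
    est = MultiTraitScan(fdr_level=fdr_level, max_abs_t=max_abs_t).fit(single_trait_results)
    return est.results_, est.threshold_
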