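"""Marker-inferred kinship (VanRaden method 1) and genotype PCA for structure."""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .genotypes import GenotypeMatrix

__all__ = ["vanraden_kinship", "GenotypePCA", "pca"]


def vanraden_kinship(genotypes: GenotypeMatrix | np.ndarray) -> np.ndarray:
    """VanRaden method-1 genomic relationship matrix.

    G_ij = sum_k (g_ik - 2 p_k)(g_jk - 2 p_k) / (2 sum_k p_k (1 - p_k)),
    with p_k the observed B-allele frequency.  Missing entries are imputed
    to the per-SNP mean first; SNPs with zero variance after imputation
    contribute nothing and are dropped from the scaling sum.  Under HWE the
    diagonal averages ~1.
    """
    if isinstance(genotypes, GenotypeMatrix):
        G = genotypes.imputed()
    else:
        G = np.asarray(genotypes, dtype=float)
        if np.isnan(G).any():
            mu = np.nanmean(G, axis=0)
            idx = np.where(np.isnan(G))
            G = G.copy()
            G[idx] = mu[idx[1]]
    p = G.mean(axis=0) / 2.0
    poly = (p > 0) & (p < 1)
    if not poly.any():
        raise ValueError("no polymorphic SNPs: kinship undefined")
    Z = G[:, poly] - 2.0 * p[poly]
    denom = 2.0 * float(np.sum(p[poly] * (1.0 - p[poly])))
    K = (Z @ Z.T) / denom
    return (K + K.T) / 2.0


class GenotypePCA(TransformerMixin, BaseEstimator):
    """Principal components of the centered (optionally standardised) genotypes.

    Components are eigenvectors of the sample covariance of individuals,
    ordered by decreasing eigenvalue; the sign convention makes the
    largest-magnitude loading of each component positive, so results are
    deterministic.  ``scale=True`` divides each SNP by its sample standard
    deviation after centering.
    """

    def __init__(self, n_components: int = 3, scale: bool = True):
        self.n_components = n_components
        self.scale = scale

    def fit(self, X: GenotypeMatrix | np.ndarray, y=None):
        G = X.imputed() if isinstance(X, GenotypeMatrix) else np.asarray(X, dtype=float)
        n = G.shape[0]
        if self.n_components > n:
            raise ValueError(f"n_components={self.n_components} exceeds n={n}")
        Z = G - G.mean(axis=0)
        if self.scale:
            sd = Z.std(axis=0, ddof=1)
            sd[sd == 0] = 1.0
            Z = Z / sd
        # SVD of the centered matrix: left singular vectors are the sample PCs
        U, s, _ = np.linalg.svd(Z, full_matrices=False)
        var = s**2
        total = float(var.sum())
        k = self.n_components
        comps = U[:, :k]
        flip = np.sign(comps[np.argmax(np.abs(comps), axis=0), np.arange(k)])
        flip[flip == 0] = 1.0
        self.components_ = comps * flip
        self.explained_variance_ratio_ = var[:k] / total if total > 0 else np.zeros(k)
        self.singular_values_ = s[:k]
        return self

    def transform(self, X=None) -> np.ndarray:
        return self.components_


def pca(genotypes: GenotypeMatrix, n_components: int = 3, scale: bool = True):
    """Top-k sample eigenvectors and explained-variance fractions."""
    est = GenotypePCA(n_components=n_components, scale=scale).fit(genotypes)
    ids = genotypes.sample_ids if isinstance(genotypes, GenotypeMatrix) else None
    table = pd.DataFrame(est.components_,
                         columns=[f"PC{i + 1}" for i in range(n_components)])
    if ids is not None:
        table.insert(0, "id", ids)
    return table, est.explained_variance_ratio_
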