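"""Single-trait mixed-linear-model association scan.

The model per trait is

    y = W s + X beta + u + e,    u ~ N(0, K sigma_g^2),  e ~ N(0, I sigma_e^2)

with W the per-SNP additive genotype column, X the fixed covariates
(intercept + leading principal components) and K the marker-inferred
kinship.  Variance components are estimated once by REML under the no-SNP
model via a single spectral decomposition of K and a one-dimensional
profile over the variance ratio, then held fixed for the scan (the
P3D/EMMAX scheme); each SNP is tested by generalised least squares in the
kinship-rotated space, with the residual scale re-estimated per SNP so the
statistic is an exact t-test when K = I.

The module also houses the empirical FDR p-value cutoff
(threshold = FDR x #{p < 0.05} / m) and a bivariate maximum-likelihood
estimator of the genetic correlation between two traits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .genotypes import GenotypeMatrix

__all__ = ["VarianceComponents", "FdrThreshold", "MixedModelGWAS",
           "estimate_variance_components", "snp_scan", "fdr_threshold",
           "genetic_correlation", "GeneticCorrelation"]


# ---------------------------------------------------------------------------
# REML variance components (EMMA-style spectral profile)
# ---------------------------------------------------------------------------

@dataclass
class VarianceComponents:
    sigma_g2: float
    sigma_e2: float
    heritability: float
    loglik: float
    boundary: bool          # ratio pinned at the search edge
    ratio: float            # sigma_g2 / sigma_e2


def _eigen_kinship(K: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    K = np.asarray(K, dtype=float)
    if not np.allclose(K, K.T, atol=1e-8):
        raise ValueError("kinship matrix must be symmetric")
    s, U = np.linalg.eigh((K + K.T) / 2.0)
    if s.min() < -1e-6:
        raise ValueError(f"kinship not PSD after stabilisation (min eigenvalue {s.min():.3g})")
    return np.clip(s, 0.0, None), U


def _reml_loglik(log_ratio: float, s: np.ndarray, ys: np.ndarray, Xs: np.ndarray,
                 logdet_xtx: float) -> float:
    """Restricted log-likelihood profiled over sigma_e^2 at a fixed ratio."""
    lam = np.exp(log_ratio)
    H = lam * s + 1.0
    Wt = 1.0 / H
    XtWX = Xs.T @ (Xs * Wt[:, None])
    XtWy = Xs.T @ (ys * Wt)
    try:
        beta = np.linalg.solve(XtWX, XtWy)
    except np.linalg.LinAlgError:
        return -np.inf
    r = ys - Xs @ beta
    rss = float(np.sum(Wt * r * r))
    n, c = Xs.shape
    nc = n - c
    if rss <= 0:
        return -np.inf
    sign, logdet_XtWX = np.linalg.slogdet(XtWX)
    if sign <= 0:
        return -np.inf
    sigma_e2 = rss / nc
    return -0.5 * (nc * (np.log(2 * np.pi * sigma_e2) + 1.0)
                   + float(np.sum(np.log(H))) + logdet_XtWX - logdet_xtx)


def estimate_variance_components(y, X, K, *, _eig=None) -> VarianceComponents:
    """REML polygenic/residual variances via a 1-D profile over the ratio.

    A coarse grid over log(sigma_g^2 / sigma_e^2) in [-12, 12] followed by
    local Brent refinement; boundary estimates are flagged rather than
    rejected (heritability then sits at ~0 or ~1).
    """
    y = np.asarray(y, dtype=float).reshape(-1)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != y.size:
        raise ValueError("y and X have mismatched rows")
    n, c = X.shape
    if n < c + 2:
        raise ValueError("too few observations for the covariate count")
    s, U = _eigen_kinship(K) if _eig is None else _eig
    ys = U.T @ y
    Xs = U.T @ X
    sign, logdet_xtx = np.linalg.slogdet(X.T @ X)

    lo, hi = -12.0, 12.0
    grid = np.linspace(lo, hi, 81)
    vals = np.array([_reml_loglik(g, s, ys, Xs, logdet_xtx) for g in grid])
    best = int(np.argmax(vals))
    a = grid[max(best - 1, 0)]
    b = grid[min(best + 1, len(grid) - 1)]
    res = optimize.minimize_scalar(lambda g: -_reml_loglik(g, s, ys, Xs, logdet_xtx),
                                   bounds=(a, b), method="bounded",
                                   options={"xatol": 1e-6})
    log_ratio = float(res.x)
    ll = -float(res.fun)
    lam = np.exp(log_ratio)
    H = lam * s + 1.0
    Wt = 1.0 / H
    XtWX = Xs.T @ (Xs * Wt[:, None])
    beta = np.linalg.solve(XtWX, Xs.T @ (ys * Wt))
    r = ys - Xs @ beta
    sigma_e2 = float(np.sum(Wt * r * r)) / (n - c)
    sigma_g2 = lam * sigma_e2
    boundary = log_ratio <= lo + 0.5 or log_ratio >= hi - 0.5
    h2 = sigma_g2 / (sigma_g2 + sigma_e2)
    return VarianceComponents(sigma_g2=sigma_g2, sigma_e2=sigma_e2, heritability=h2,
                              loglik=ll, boundary=boundary, ratio=lam)


# ---------------------------------------------------------------------------
# association scan
# ---------------------------------------------------------------------------

class MixedModelGWAS(BaseEstimator):
    """P3D mixed-model scan over all SNP columns.

    Parameters
    ----------
    exact_reml : bool
        Re-estimate variance components per SNP (slow; small data only).
        Default False: the no-SNP REML ratio is reused for every SNP.

    After ``fit(genotypes, y, covariates=..., kinship=...)`` the per-SNP
    table is in ``results_`` (columns snp_id, chrom, pos, effect, se, t,
    p, n_used, note) and the null-model components in ``varcomp_``.
    """

    def __init__(self, exact_reml: bool = False):
        self.exact_reml = exact_reml

    def fit(self, genotypes, y, covariates=None, kinship=None):
        if isinstance(genotypes, GenotypeMatrix):
            G = genotypes.imputed()
            snp_map = genotypes.snp_map
        else:
            G = np.asarray(genotypes, dtype=float)
            if np.isnan(G).any():
                mu = np.nanmean(G, axis=0)
                idx = np.where(np.isnan(G))
                G = G.copy()
                G[idx] = mu[idx[1]]
            snp_map = pd.DataFrame({"chrom": 0, "pos": np.arange(G.shape[1]),
                                    "snp_id": [f"snp{j + 1}" for j in range(G.shape[1])]})
        y = np.asarray(y, dtype=float).reshape(-1)
        n, m = G.shape
        if y.size != n:
            raise ValueError("phenotype length does not match genotype rows")
        X = (np.ones((n, 1)) if covariates is None
             else np.column_stack([np.ones(n), np.atleast_2d(np.asarray(covariates, dtype=float))]))
        if covariates is not None and np.asarray(covariates).shape[0] != n:
            raise ValueError("covariate rows do not match genotype rows")
        K = np.eye(n) if kinship is None else np.asarray(kinship, dtype=float)

        s, U = _eigen_kinship(K)
        vc = estimate_variance_components(y, X, K, _eig=(s, U))
        self.varcomp_ = vc

        if self.exact_reml:
            eff, se, tval, pval, note = self._scan_exact(G, y, X, (s, U))
        else:
            eff, se, tval, pval, note = self._scan_p3d(G, y, X, s, U, vc.ratio)

        self.results_ = pd.DataFrame({
            "snp_id": snp_map["snp_id"].to_numpy(),
            "chrom": snp_map["chrom"].to_numpy(),
            "pos": snp_map["pos"].to_numpy(),
            "effect": eff, "se": se, "t": tval, "p": pval,
            "n_used": n, "note": note,
        })
        return self

    @staticmethod
    def _scan_p3d(G, y, X, s, U, ratio):
        n, m = G.shape
        c = X.shape[1]
        df = n - c - 1
        if df <= 0:
            raise ValueError("not enough observations for the t-test df")
        sw = np.sqrt(1.0 / (ratio * s + 1.0))
        Xw = (U.T @ X) * sw[:, None]
        yw = (U.T @ y) * sw
        Gw = (U.T @ G) * sw[:, None]
        Q, _ = np.linalg.qr(Xw)
        yr = yw - Q @ (Q.T @ yw)
        Gr = Gw - Q @ (Q.T @ Gw)
        gg = np.einsum("ij,ij->j", Gr, Gr)
        gy = Gr.T @ yr
        yy = float(yr @ yr)
        # SNPs collinear with the covariates (incl. monomorphic) have ~zero
        # residual variance and get NA rows rather than spurious statistics
        tol = 1e-10 * max(float(gg.max(initial=0.0)), 1.0)
        bad = gg <= tol
        gg_safe = np.where(bad, 1.0, gg)
        eff = gy / gg_safe
        rss = np.maximum(yy - eff * gy, 0.0)
        sigma2 = rss / df
        se = np.sqrt(sigma2 / gg_safe)
        with np.errstate(divide="ignore", invalid="ignore"):
            tval = eff / se
        pval = 2.0 * stats.t.sf(np.abs(tval), df)
        note = np.where(bad, "monomorphic_or_collinear", "")
        for arr in (eff, se, tval, pval):
            arr[bad] = np.nan
        return eff, se, tval, pval, note

    def _scan_exact(self, G, y, X, eig):
        n, m = G.shape
        eff = np.full(m, np.nan)
        se = np.full(m, np.nan)
        tval = np.full(m, np.nan)
        pval = np.full(m, np.nan)
        note = np.empty(m, dtype=object)
        note[:] = ""
        s, U = eig
        for j in range(m):
            g = G[:, j]
            Xj = np.column_stack([X, g])
            if np.linalg.matrix_rank(Xj) <= X.shape[1]:
                note[j] = "monomorphic_or_collinear"
                continue
            vc = estimate_variance_components(y, Xj, None, _eig=eig)
            sw = np.sqrt(1.0 / (vc.ratio * s + 1.0))
            Xw = (U.T @ Xj) * sw[:, None]
            yw = (U.T @ y) * sw
            XtX = Xw.T @ Xw
            beta = np.linalg.solve(XtX, Xw.T @ yw)
            r = yw - Xw @ beta
            df = n - Xj.shape[1]
            sigma2 = float(r @ r) / df
            cov = sigma2 * np.linalg.inv(XtX)
            eff[j] = beta[-1]
            se[j] = np.sqrt(cov[-1, -1])
            tval[j] = eff[j] / se[j]
            pval[j] = 2.0 * stats.t.sf(abs(tval[j]), df)
        return eff, se, tval, pval, note


def snp_scan(genotypes, y, covariates=None, kinship=None,
             exact_reml: bool = False) -> pd.DataFrame:
    """Per-SNP effect, SE, t and p (thin wrapper over :class:`MixedModelGWAS`)."""
    est = MixedModelGWAS(exact_reml=exact_reml).fit(genotypes, y,
                                                    covariates=covariates, kinship=kinship)
    return est.results_


# ---------------------------------------------------------------------------
# FDR threshold
# ---------------------------------------------------------------------------

@dataclass
class FdrThreshold:
    fdr_level: float
    n_below_005: int
    m_total: int
    p_threshold: float

    @property
    def n(self):
        return self.n_below_005

    @property
    def m(self):
        return self.m_total


def fdr_threshold(p_values, fdr_level: float = 0.05) -> tuple[FdrThreshold, np.ndarray]:
    """Empirical FDR p-value cutoff: threshold = FDR x #{p < 0.05} / m.

    Returns the threshold record and the boolean pass mask (p <= threshold).
    This equals the Benjamini-Hochberg critical value evaluated at rank
    n = #{p < 0.05}, not the full step-up procedure; with n = m it
    collapses to the FDR level itself.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        raise ValueError("empty p-value vector")
    finite = p[~np.isnan(p)]
    m = p.size
    n_below = int(np.sum(finite < 0.05))
    thr = fdr_level * n_below / m
    passes = np.where(np.isnan(p), False, p <= thr) if thr > 0 else np.zeros(m, dtype=bool)
    return FdrThreshold(fdr_level=fdr_level, n_below_005=n_below,
                        m_total=m, p_threshold=thr), passes


# ---------------------------------------------------------------------------
# bivariate genetic correlation
# ---------------------------------------------------------------------------

@dataclass
class GeneticCorrelation:
    r_g: float
    sigma_g: np.ndarray     # 2x2 additive covariance
    sigma_e: np.ndarray     # 2x2 residual covariance
    loglik: float
    defined: bool           # False when a genetic variance hit the zero boundary


def _chol_build(th):
    L = np.array([[np.exp(th[0]), 0.0], [th[1], np.exp(th[2])]])
    return L @ L.T


def genetic_correlation(y1, y2, covariates=None, kinship=None) -> GeneticCorrelation:
    """Genetic correlation of two traits on shared individuals.

    Both traits are rotated into the kinship eigenbasis and residualised
    on the fixed covariates there; the 2x2 genetic and residual covariance
    matrices are then estimated by numerical maximum likelihood (each
    rotated pair is independent with covariance Sigma_g * s_i + Sigma_e),
    and r_g = cov_g / sqrt(var_g1 var_g2), clamped to [-1, 1].  A genetic
    variance at the zero boundary leaves r_g undefined (NaN, flagged).
    """
    y1 = np.asarray(y1, dtype=float).reshape(-1)
    y2 = np.asarray(y2, dtype=float).reshape(-1)
    if y1.size != y2.size:
        raise ValueError("traits must cover the same individuals")
    n = y1.size
    X = (np.ones((n, 1)) if covariates is None
         else np.column_stack([np.ones(n), np.atleast_2d(np.asarray(covariates, dtype=float))]))
    K = np.eye(n) if kinship is None else np.asarray(kinship, dtype=float)
    s, U = _eigen_kinship(K)
    Xs = U.T @ X
    Q, _ = np.linalg.qr(Xs)

    def rot_resid(y):
        ys = U.T @ y
        return ys - Q @ (Q.T @ ys)

    r1, r2 = rot_resid(y1), rot_resid(y2)

    # moment/REML starts
    vc1 = estimate_variance_components(y1, X, None, _eig=(s, U))
    vc2 = estimate_variance_components(y2, X, None, _eig=(s, U))
    rho = float(np.corrcoef(r1, r2)[0, 1]) if np.std(r1) > 0 and np.std(r2) > 0 else 0.0
    rho = np.clip(rho, -0.9, 0.9)

    def chol_params(Sig):
        Sig = Sig + 1e-8 * np.eye(2) * np.trace(Sig)
        L = np.linalg.cholesky(Sig)
        return [np.log(L[0, 0]), L[1, 0], np.log(L[1, 1])]

    Sg0 = np.array([[max(vc1.sigma_g2, 1e-4 * np.var(y1)), rho * np.sqrt(max(vc1.sigma_g2, 1e-12) * max(vc2.sigma_g2, 1e-12))],
                    [0.0, max(vc2.sigma_g2, 1e-4 * np.var(y2))]])
    Sg0[1, 0] = Sg0[0, 1]
    Se0 = np.array([[max(vc1.sigma_e2, 1e-4 * np.var(y1)), rho * np.sqrt(vc1.sigma_e2 * vc2.sigma_e2)],
                    [0.0, max(vc2.sigma_e2, 1e-4 * np.var(y2))]])
    Se0[1, 0] = Se0[0, 1]
    th0 = np.array(chol_params(Sg0) + chol_params(Se0))

    r1sq, r2sq, r12 = r1 * r1, r2 * r2, r1 * r2

    def nll(th):
        Sg = _chol_build(th[:3])
        Se = _chol_build(th[3:])
        c11 = Sg[0, 0] * s + Se[0, 0]
        c12 = Sg[0, 1] * s + Se[0, 1]
        c22 = Sg[1, 1] * s + Se[1, 1]
        det = c11 * c22 - c12 * c12
        if np.any(det <= 0) or np.any(c11 <= 0):
            return 1e12
        quad = (c22 * r1sq - 2 * c12 * r12 + c11 * r2sq) / det
        return 0.5 * float(np.sum(np.log(det) + quad))

    res = optimize.minimize(nll, th0, method="Nelder-Mead",
                            options={"maxiter": 4000, "xatol": 1e-8, "fatol": 1e-8})
    Sg = _chol_build(res.x[:3])
    Se = _chol_build(res.x[3:])
    tot1 = Sg[0, 0] + Se[0, 0]
    tot2 = Sg[1, 1] + Se[1, 1]
    defined = Sg[0, 0] > 1e-6 * tot1 and Sg[1, 1] > 1e-6 * tot2
    rg = float(np.clip(Sg[0, 1] / np.sqrt(Sg[0, 0] * Sg[1, 1]), -1.0, 1.0)) if defined else float("nan")
    return GeneticCorrelation(r_g=rg, sigma_g=Sg, sigma_e=Se,
                              loglik=-float(res.fun), defined=defined)
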