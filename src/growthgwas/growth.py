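"""Nonlinear growth models and per-individual least-squares fitting.

Three classical three-parameter growth functions describe body weight W (kg)
as a function of age t (months):

    Gompertz   W = A * exp(-b * exp(-K t))
    Logistic   W = A / (1 + b * exp(-K t))
    Brody      W = A * (1 - b * exp(-K t))

A is the mature (asymptotic) body weight, b a dimensionless time-scale
parameter and K the maturity rate (1/month).  Fitting is Gauss-Newton with
an analytic Jacobian and Levenberg damping engaged whenever a plain step
would increase the residual sum of squares.  The fitted (A, b, K) triples
are the phenotypes consumed by the association modules.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, RegressorMixin

MODELS = ("gompertz", "logistic", "brody")

__all__ = [
    "MODELS",
    "CurveFit",
    "GrowthCurveModel",
    "predict_weight",
    "fit_curve",
    "r_squared",
    "fit_population",
    "parameter_correlations",
]


def _check_model(model: str) -> str:
    if model not in MODELS:
        raise ValueError(f"unknown growth model {model!r}; expected one of {MODELS}")
    return model


def predict_weight(model: str, A: float, b, K: float, t):
    """Evaluate a growth model at age(s) ``t`` months.

    Requires A > 0 and K > 0; b may be any real.  Vectorised over ``t``.
    """
    _check_model(model)
    if A <= 0 or K <= 0:
        raise ValueError("A and K must be strictly positive")
    t = np.asarray(t, dtype=float)
    u = np.exp(-K * t)
    if model == "gompertz":
        out = A * np.exp(-b * u)
    elif model == "logistic":
        out = A / (1.0 + b * u)
    else:  # brody
        out = A * (1.0 - b * u)
    return out if out.ndim else float(out)


def _model_jacobian(model: str, theta: np.ndarray, t: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Fitted values and the n x 3 Jacobian d f / d (A, b, K)."""
    A, b, K = theta
    u = np.exp(-K * t)
    if model == "gompertz":
        e = np.exp(-b * u)
        f = A * e
        J = np.column_stack([e, -A * u * e, A * b * t * u * e])
    elif model == "logistic":
        d = 1.0 + b * u
        f = A / d
        J = np.column_stack([1.0 / d, -A * u / d**2, A * b * t * u / d**2])
    else:
        f = A * (1.0 - b * u)
        J = np.column_stack([1.0 - b * u, -A * u, A * b * t * u])
    return f, J


@dataclass
class CurveFit:
    """Result of fitting one growth model to one individual's weight series."""

    model: str
    A: float
    b: float
    K: float
    rss: float
    r_squared: float
    n_obs: int
    converged: bool
    n_iter: int
    individual_id: object = None

    def predict(self, t):
        return predict_weight(self.model, self.A, self.b, self.K, t)


def r_squared(observed, fitted) -> float:
    """Coefficient of determination, 1 - SSE/SST.

    Undefined (raises) when the observed values are constant, since the
    total sum of squares about the mean vanishes.
    """
    obs = np.asarray(observed, dtype=float)
    fit = np.asarray(fitted, dtype=float)
    if obs.shape != fit.shape:
        raise ValueError("observed and fitted must have equal length")
    if obs.size < 2:
        raise ValueError("need at least two observations")
    sst = float(np.sum((obs - obs.mean()) ** 2))
    if sst <= 0.0:
        raise ValueError("constant observed vector: R^2 undefined (SST = 0)")
    sse = float(np.sum((obs - fit) ** 2))
    return 1.0 - sse / sst


# ---------------------------------------------------------------------------
# initialization
# ---------------------------------------------------------------------------

# A0 ladders as multiples of the largest observed weight.  The asymptote of
# the Brody form is typically far above the data range (it is weakly
# identified from a truncated series), so its ladder reaches higher.
_A0_MULTIPLIERS = {
    "gompertz": (1.05, 1.2, 1.5),
    "logistic": (1.05, 1.2, 1.5),
    "brody": (1.2, 1.7, 2.5, 4.0, 6.0),
}


def _linearized_start(model: str, t: np.ndarray, w: np.ndarray, A0: float):
    """(b0, K0) from log-linearising the model at a pinned asymptote A0.

    Each form can be rearranged to  g(W; A0) = ln b - K t  for a model-
    specific transform g; an ordinary regression of g on t yields the pair.
    Points incompatible with A0 (W >= A0) are dropped; None when fewer than
    two usable points remain or the slope implies K <= 0.
    """
    with np.errstate(divide="ignore", invalid="ignore"):
        if model == "gompertz":
            ratio = np.log(A0 / w)
            g = np.where(ratio > 0, np.log(np.maximum(ratio, 1e-300)), np.nan)
        elif model == "logistic":
            ratio = A0 / w - 1.0
            g = np.where(ratio > 0, np.log(np.maximum(ratio, 1e-300)), np.nan)
        else:
            ratio = 1.0 - w / A0
            g = np.where(ratio > 0, np.log(np.maximum(ratio, 1e-300)), np.nan)
    ok = np.isfinite(g)
    if ok.sum() < 2:
        return None
    slope, intercept = np.polyfit(t[ok], g[ok], 1)
    K0 = -slope
    if not np.isfinite(K0) or K0 <= 0:
        return None
    b0 = float(np.exp(intercept))
    return b0, K0


def _initial_points(model: str, t: np.ndarray, w: np.ndarray) -> list[np.ndarray]:
    wmax = float(w.max())
    starts = []
    for mult in _A0_MULTIPLIERS[model]:
        A0 = mult * wmax
        lin = _linearized_start(model, t, w, A0)
        if lin is not None:
            starts.append(np.array([A0, lin[0], lin[1]]))
    if not starts:  # last-ditch generic start
        starts.append(np.array([1.2 * wmax, 1.0, 0.1]))
    return starts


# ---------------------------------------------------------------------------
# Gauss-Newton with Levenberg damping
# ---------------------------------------------------------------------------

def _gauss_newton(model: str, t: np.ndarray, w: np.ndarray, theta0: np.ndarray,
                  tol: float = 1e-10, max_iter: int = 100):
    """Minimise sum (w - f(t; theta))^2 from theta0.

    Plain Gauss-Newton steps; when a step increases the RSS, Levenberg
    damping (lambda * diag(J'J) added to the normal equations) is escalated
    until the RSS decreases or the damping saturates.  Convergence is a
    relative RSS change below ``tol``.
    """
    theta = theta0.astype(float).copy()
    f, J = _model_jacobian(model, theta, t)
    r = w - f
    rss = float(r @ r)
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        JtJ = J.T @ J
        Jtr = J.T @ r
        diag = np.diag(np.maximum(np.diag(JtJ), 1e-12))
        lam = 0.0
        new_theta = new_rss = None
        for _ in range(25):
            try:
                step = np.linalg.solve(JtJ + lam * diag, Jtr)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(JtJ + lam * diag, Jtr, rcond=None)[0]
            cand = theta + step
            fc, _ = _model_jacobian(model, cand, t)
            if np.all(np.isfinite(fc)):
                rc = w - fc
                cand_rss = float(rc @ rc)
                if cand_rss <= rss:
                    new_theta, new_rss = cand, cand_rss
                    break
            lam = 1e-4 if lam == 0.0 else lam * 10.0
        if new_theta is None:
            break  # damping saturated: local minimum to working precision
        rel = (rss - new_rss) / max(rss, 1e-300)
        theta, rss = new_theta, new_rss
        f, J = _model_jacobian(model, theta, t)
        r = w - f
        if rel < tol:
            converged = True
            break
    return theta, rss, converged, it


def fit_curve(ages, weights, model: str = "gompertz", init=None,
              individual_id=None, tol: float = 1e-10, max_iter: int = 100) -> CurveFit:
    """Least-squares fit of one growth model to one individual's series.

    Parameters
    ----------
    ages, weights
        Paired observation vectors (months, kg); at least three distinct
        ages are required for the three parameters.
    init
        Optional explicit (A, b, K) start; otherwise a deterministic
        model-specific multi-start (asymptote ladder + log-linearisation)
        is used and the lowest-RSS fit kept.

    A fit ending with a non-positive asymptote or maturity rate is returned
    with ``converged=False``: the parameters are biologically positive.
    """
    _check_model(model)
    t = np.asarray(ages, dtype=float)
    w = np.asarray(weights, dtype=float)
    if t.shape != w.shape or t.ndim != 1:
        raise ValueError("ages and weights must be 1-D and of equal length")
    if np.unique(t).size < 3:
        raise ValueError("need at least 3 distinct ages to fit 3 parameters")
    if np.any(w <= 0):
        raise ValueError("weights must be positive")

    starts = [np.asarray(init, dtype=float)] if init is not None else _initial_points(model, t, w)
    best = None
    for theta0 in starts:
        theta, rss, conv, it = _gauss_newton(model, t, w, theta0, tol=tol, max_iter=max_iter)
        key = (not conv, rss)  # prefer converged, then lower RSS
        if best is None or key < best[0]:
            best = (key, theta, rss, conv, it)
    _, theta, rss, conv, it = best
    A, b, K = (float(x) for x in theta)
    if A <= 0 or K <= 0:
        conv = False
    fitted = _model_jacobian(model, theta, t)[0]
    try:
        r2 = r_squared(w, fitted)
    except ValueError:
        r2 = float("nan")
    return CurveFit(model=model, A=A, b=b, K=K, rss=float(rss), r_squared=r2,
                    n_obs=int(t.size), converged=bool(conv), n_iter=it,
                    individual_id=individual_id)


class GrowthCurveModel(RegressorMixin, BaseEstimator):
    """Scikit-learn style wrapper around :func:`fit_curve`.

    ``fit(X, y)`` takes ages (n,) or (n, 1) and weights (n,), exposing the
    fitted parameters as ``A_``, ``b_``, ``K_`` plus diagnostics, and
    ``predict(X)`` evaluates the fitted curve.
    """

    def __init__(self, model: str = "gompertz", init=None, tol: float = 1e-10,
                 max_iter: int = 100):
        self.model = model
        self.init = init
        self.tol = tol
        self.max_iter = max_iter

    def fit(self, X, y):
        t = np.asarray(X, dtype=float).reshape(-1)
        res = fit_curve(t, y, model=self.model, init=self.init,
                        tol=self.tol, max_iter=self.max_iter)
        self.A_, self.b_, self.K_ = res.A, res.b, res.K
        self.rss_ = res.rss
        self.r_squared_ = res.r_squared
        self.converged_ = res.converged
        self.n_iter_ = res.n_iter
        self.result_ = res
        return self

    def predict(self, X):
        t = np.asarray(X, dtype=float).reshape(-1)
        return predict_weight(self.model, self.A_, self.b_, self.K_, t)


# ---------------------------------------------------------------------------
# population-level fitting
# ---------------------------------------------------------------------------

@dataclass
class PopulationFit:
    """Per-individual fits for every model plus the pooled comparison."""

    fits: pd.DataFrame              # id, model, A, b, K, rss, r_squared, converged, n_iter
    pooled_r2: dict[str, float] = field(default_factory=dict)
    selected_model: str = ""
    phenotypes: pd.DataFrame = None  # id, A, b, K for the selected model
    n_failed: dict[str, int] = field(default_factory=dict)


def fit_population(records: pd.DataFrame, models=MODELS) -> PopulationFit:
    """Fit each model to every individual and select by pooled R^2.

    ``records`` is long-format with columns id, age_months, weight_kg
    (already pre-adjusted for fixed effects).  The pooled R^2 for a model
    is computed from all individuals' residuals jointly against the grand
    mean of all observations, which yields one goodness-of-fit number per
    model for the whole population.  The winning model's converged (A, b, K)
    estimates become the association phenotypes; individuals that fail for
    the winner are excluded and counted.
    """
    rows, pooled, n_failed = [], {}, {}
    grand = records["weight_kg"].to_numpy(dtype=float)
    sst = float(np.sum((grand - grand.mean()) ** 2))
    grouped = list(records.groupby("id", sort=True))
    usable_models = []
    for model in models:
        _check_model(model)
        sse = 0.0
        n_ok = 0
        for ind, sub in grouped:
            t = sub["age_months"].to_numpy(dtype=float)
            w = sub["weight_kg"].to_numpy(dtype=float)
            try:
                fit = fit_curve(t, w, model=model, individual_id=ind)
            except ValueError:
                n_failed[model] = n_failed.get(model, 0) + 1
                continue
            rows.append({"id": ind, "model": model, "A": fit.A, "b": fit.b,
                         "K": fit.K, "rss": fit.rss, "r_squared": fit.r_squared,
                         "converged": fit.converged, "n_iter": fit.n_iter})
            if fit.converged:
                sse += fit.rss
                n_ok += 1
            else:
                n_failed[model] = n_failed.get(model, 0) + 1
        if n_ok == 0:
            warnings.warn(f"model {model!r}: no individual converged; excluded from comparison")
            continue
        pooled[model] = 1.0 - sse / sst if sst > 0 else float("nan")
        usable_models.append(model)
    if not usable_models:
        raise RuntimeError("every model failed on every individual")
    fits = pd.DataFrame(rows)
    selected = max(usable_models, key=lambda m: pooled[m])
    sel = fits[(fits["model"] == selected) & fits["converged"]]
    phenos = sel[["id", "A", "b", "K"]].reset_index(drop=True)
    return PopulationFit(fits=fits, pooled_r2=pooled, selected_model=selected,
                         phenotypes=phenos, n_failed=n_failed)


def parameter_correlations(params: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation matrix of the (A, b, K) parameter phenotypes.

    Complete rows only; a zero-variance column yields NaN entries with a
    warning rather than an error, since downstream reporting tolerates it.
    """
    cols = ["A", "b", "K"]
    sub = params[cols].dropna()
    if len(sub) < 3:
        raise ValueError("need at least 3 complete rows")
    sd = sub.std(ddof=1)
    if (sd == 0).any():
        warnings.warn(f"zero-variance column(s): {list(sd.index[sd == 0])}; correlations undefined")
    with np.errstate(divide="ignore", invalid="ignore"):
        corr = sub.corr(method="pearson")
    return corr
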