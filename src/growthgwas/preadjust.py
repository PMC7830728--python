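"""Fixed-effect pre-adjustment of raw weights before curve fitting.

Weights at each age are adjusted for breed, birth year and birth month with
an ordinary least-squares model on categorical factors (a Gaussian
identity-link GLM), one model per age stratum.  The adjusted weight is the
OLS residual plus the stratum grand mean, which removes factor shifts while
keeping weights on the kg scale the growth models expect.  The operation is
idempotent and preserves each stratum's mean.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

DEFAULT_FACTORS = ("breed", "birth_year", "birth_month")

__all__ = ["DEFAULT_FACTORS", "FixedEffectAdjuster", "adjust_weights"]


def _design(sub: pd.DataFrame, factors) -> tuple[np.ndarray, list[str]]:
    """Intercept + first-level-reference dummy design for the factors."""
    cols = [np.ones(len(sub))]
    names = ["intercept"]
    for f in factors:
        levels = sorted(sub[f].astype(str).unique())
        for lev in levels[1:]:
            cols.append((sub[f].astype(str) == lev).to_numpy(dtype=float))
            names.append(f"{f}[{lev}]")
    return np.column_stack(cols), names


class FixedEffectAdjuster(TransformerMixin, BaseEstimator):
    """Per-age OLS adjustment transformer for long-format weight records.

    ``transform`` returns the records with ``weight_kg`` replaced by the
    adjusted value; ``effects_`` holds the per-age coefficient table.
    Rank-deficient (confounded) designs are handled by the minimum-norm
    least-squares solution, which drops aliased directions; strata with no
    more records than estimable effects pass through unadjusted with a
    warning.
    """

    def __init__(self, factors=DEFAULT_FACTORS):
        self.factors = tuple(factors)

    def fit(self, X: pd.DataFrame, y=None):
        for f in self.factors:
            if f not in X.columns:
                raise ValueError(f"records lack fixed-effect column {f!r}")
            if X[f].isna().any():
                raise ValueError(f"fixed-effect column {f!r} contains missing levels")
        return self

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        self.fit(X)
        out = X.copy()
        effect_rows = []
        for age, sub in X.groupby("age_months", sort=True):
            D, names = _design(sub, self.factors)
            rank = np.linalg.matrix_rank(D)
            if len(sub) <= rank:
                warnings.warn(f"age stratum {age}: too few records ({len(sub)}) "
                              f"for {rank} effects; passed through unadjusted")
                continue
            w = sub["weight_kg"].to_numpy(dtype=float)
            beta, _, D_rank, _ = np.linalg.lstsq(D, w, rcond=None)
            if D_rank < D.shape[1]:
                warnings.warn(f"age stratum {age}: rank-deficient design "
                              f"({D_rank} < {D.shape[1]}); aliased effects dropped")
            resid = w - D @ beta
            out.loc[sub.index, "weight_kg"] = resid + w.mean()
            for nm, est in zip(names, beta):
                effect_rows.append({"age_months": age, "term": nm, "estimate": est})
        self.effects_ = pd.DataFrame(effect_rows)
        return out


def adjust_weights(records: pd.DataFrame, factors=DEFAULT_FACTORS):
    """Adjusted records plus the per-age effect-estimate table."""
    adj = FixedEffectAdjuster(factors=factors)
    out = adj.transform(records)
    return out, adj.effects_
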