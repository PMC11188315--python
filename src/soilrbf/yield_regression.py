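"""Forward stepwise multiple linear regression for yield prediction.

Builds Y = e0 + e1·X1 + … + ez·Xz by iteratively adding the candidate
predictor with the smallest partial-F p-value below ``alpha_enter`` (ties
broken by candidate column order), then removing any included predictor
whose p-value exceeds ``alpha_remove``, until no candidate can enter.  The
partial F-test for a single added variable is equivalent to the t-test on
its coefficient, which is what the OLS fit reports.

The default candidate set for yield modelling is the three soil nutrient
contents; fertilizer application rates can be added by the caller.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = ["StepwiseModel", "forward_stepwise", "predict_yield"]

logger = logging.getLogger(__name__)


@dataclass
class StepwiseModel:
    """Fitted stepwise linear model: intercept e0 and per-predictor coefficients."""

    intercept: float
    coefficients: dict[str, float]
    alpha_enter: float
    alpha_remove: float
    r2: float
    residual_variance: float
    history: list[dict] = field(default_factory=list)

    @property
    def selected(self) -> list[str]:
        return list(self.coefficients)

    @property
    def z(self) -> int:
        return len(self.coefficients)

    def to_dict(self) -> dict:
        """JSON-ready document: coefficients, thresholds, diagnostics, history."""
        return {
            "intercept": self.intercept,
            "coefficients": dict(self.coefficients),
            "alpha_enter": self.alpha_enter,
            "alpha_remove": self.alpha_remove,
            "r2": self.r2,
            "residual_variance": self.residual_variance,
            "history": list(self.history),
        }


def _fit_ols(X: pd.DataFrame, y, cols: list[str]):
    design = sm.add_constant(X[cols], has_constant="add") if cols else (
        pd.DataFrame({"const": np.ones(len(X))}, index=X.index)
    )
    return sm.OLS(np.asarray(y, dtype=float), design).fit()


def forward_stepwise(X, y, alpha_enter: float = 0.05,
                     alpha_remove: float = 0.10) -> StepwiseModel:
    """Run forward stepwise selection with backward elimination.

    Parameters
    ----------
    X
        Candidate predictor matrix (DataFrame, one column per candidate, or
        2-D array — columns are then named ``X1..Xp``).
    y
        Response vector (yield).
    alpha_enter, alpha_remove
        Entry and removal significance thresholds; ``alpha_enter`` must not
        exceed ``alpha_remove`` or the loop could cycle.
    """
    if not isinstance(X, pd.DataFrame):
        arr = np.atleast_2d(np.asarray(X, dtype=float))
        X = pd.DataFrame(arr, columns=[f"X{j + 1}" for j in range(arr.shape[1])])
    y = np.asarray(y, dtype=float).ravel()
    if alpha_enter > alpha_remove:
        raise ValueError("alpha_enter must be <= alpha_remove")
    candidates = list(X.columns)
    if len(X) <= len(candidates) + 1:
        raise ValueError("need n > number of candidates + 1")
    usable = []
    for c in candidates:
        if float(X[c].var()) == 0.0:
            warnings.warn(f"candidate {c!r} has zero variance; excluded", stacklevel=2)
            logger.warning("excluding zero-variance candidate %r", c)
        else:
            usable.append(c)

    included: list[str] = []
    history: list[dict] = []
    while True:
        # a (numerically) perfect fit leaves no residual variation: partial
        # F-tests degenerate to 0/0, so no further candidate can enter
        if included:
            cur = _fit_ols(X, y, included)
            if cur.rsquared > 1 - 1e-12:
                break
        # entry step: smallest p-value below alpha_enter, first-come tie-break
        best = None
        for c in usable:
            if c in included:
                continue
            fit = _fit_ols(X, y, included + [c])
            p = float(fit.pvalues[c])
            if p < alpha_enter and (best is None or p < best[1] - 1e-15):
                best = (c, p, float(fit.rsquared))
        if best is None:
            break
        included.append(best[0])
        history.append({"action": "enter", "variable": best[0],
                        "p_value": best[1], "r2": best[2]})
        logger.info("enter %s (p=%.3g, R2=%.4f)", *best)
        # removal step: drop anything whose p-value drifted above alpha_remove
        while len(included) > 0:
            fit = _fit_ols(X, y, included)
            pvals = {c: float(fit.pvalues[c]) for c in included}
            worst = max(pvals, key=lambda c: pvals[c])
            if pvals[worst] <= alpha_remove:
                break
            included.remove(worst)
            history.append({"action": "remove", "variable": worst,
                            "p_value": pvals[worst], "r2": float(fit.rsquared)})
            logger.info("remove %s (p=%.3g)", worst, pvals[worst])

    if included:
        rank = np.linalg.matrix_rank(sm.add_constant(X[included]).to_numpy())
        if rank < len(included) + 1:
            raise ValueError("final design matrix is rank-deficient")
    fit = _fit_ols(X, y, included)
    coeffs = {c: float(fit.params[c]) for c in included}
    resid = y - fit.fittedvalues
    return StepwiseModel(
        intercept=float(fit.params["const"]),
        coefficients=coeffs,
        alpha_enter=alpha_enter,
        alpha_remove=alpha_remove,
        r2=float(fit.rsquared) if included else 0.0,
        residual_variance=float(np.var(resid, ddof=len(included) + 1))
        if len(y) > len(included) + 1 else float("nan"),
        history=history,
    )


def predict_yield(model: StepwiseModel, X_new) -> np.ndarray:
    """Evaluate e0 + Σ e_i·X_i on new data (must contain all selected columns)."""
    if isinstance(X_new, pd.DataFrame):
        for c in model.selected:
            if c not in X_new.columns:
                raise ValueError(f"missing predictor column {c!r}")
        n = len(X_new)
        out = np.full(n, model.intercept, dtype=float)
        for c, e in model.coefficients.items():
            out += e * X_new[c].to_numpy(dtype=float)
        return out
    arr = np.atleast_2d(np.asarray(X_new, dtype=float))
    cols = [f"X{j + 1}" for j in range(arr.shape[1])]
    return predict_yield(model, pd.DataFrame(arr, columns=cols))
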