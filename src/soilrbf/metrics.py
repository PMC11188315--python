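"""Regression evaluation metrics and model-comparison tables.

Three metrics evaluate a predictor against held-out actuals:

* MAPE — mean absolute percentage error, ``100/t * sum(|U_j - Uhat_j| / |U_j|)``
* MAE  — mean absolute error, in target units
* R²   — coefficient of determination, ``1 - SSE/SST`` with SST taken about
  the mean of the *actual* values

Comparison tables mirror the conventional benchmark layout: one row per
metric, one column per model, plus relative-change columns showing how much
a designated subject model reduces MAPE/MAE (and raises R²) against each
competitor.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import numpy as np
import pandas as pd

__all__ = [
    "EvaluationPair",
    "MetricsReport",
    "mape",
    "mae",
    "r2",
    "relative_change",
    "comparison_table",
    "compare_models",
]

#: Actual values with magnitude below this are rejected by MAPE.
MAPE_EPS = 1e-8


@dataclass
class EvaluationPair:
    """Paired actual/predicted vectors in target units."""

    actual: np.ndarray
    predicted: np.ndarray

    def __post_init__(self) -> None:
        self.actual = np.asarray(self.actual, dtype=float).ravel()
        self.predicted = np.asarray(self.predicted, dtype=float).ravel()
        if self.actual.shape != self.predicted.shape:
            raise ValueError("actual and predicted must have equal length")
        if self.actual.size < 1:
            raise ValueError("need at least one sample")
        if not (np.isfinite(self.actual).all() and np.isfinite(self.predicted).all()):
            raise ValueError("non-finite value in evaluation pair")


def _pair(actual, predicted) -> EvaluationPair:
    if isinstance(actual, EvaluationPair):
        return actual
    return EvaluationPair(actual, predicted)


def mape(actual, predicted=None, eps: float = MAPE_EPS) -> float:
    """Mean absolute percentage error, in percent."""
    p = _pair(actual, predicted)
    if (np.abs(p.actual) < eps).any():
        raise ValueError(
            f"actual value with |U| < {eps:g}; MAPE is undefined near zero"
        )
    return 100.0 * float(np.mean(np.abs(p.actual - p.predicted) / np.abs(p.actual)))


def mae(actual, predicted=None) -> float:
    """Mean absolute error, in target units."""
    p = _pair(actual, predicted)
    return float(np.mean(np.abs(p.actual - p.predicted)))


def r2(actual, predicted=None) -> float:
    """Coefficient of determination, 1 - SSE/SST (SST about the actuals' mean)."""
    p = _pair(actual, predicted)
    sst = float(np.sum((p.actual - p.actual.mean()) ** 2))
    if sst == 0:
        raise ValueError("R^2 undefined for constant actual values (SST = 0)")
    sse = float(np.sum((p.actual - p.predicted) ** 2))
    return 1.0 - sse / sst


@dataclass
class MetricsReport:
    """MAPE (percent), MAE (target units) and R² for one model."""

    mape: float
    mae: float
    r2: float

    @classmethod
    def from_pair(cls, actual, predicted=None) -> "MetricsReport":
        p = _pair(actual, predicted)
        return cls(mape=mape(p), mae=mae(p), r2=r2(p))


def relative_change(reference: float, new: float, direction: str = "reduction") -> float:
    """Percentage change of ``new`` against ``reference``.

    ``direction="reduction"`` returns ``100*(reference - new)/reference``
    (positive when the new value is smaller, as for error metrics);
    ``direction="increase"`` returns ``100*(new - reference)/reference``
    (positive when the new value is larger, as for R²).  The raw value is
    returned; tables round to two decimals for presentation.
    """
    if reference == 0:
        raise ValueError("relative change undefined for reference = 0")
    if direction == "reduction":
        return 100.0 * (reference - new) / reference
    if direction == "increase":
        return 100.0 * (new - reference) / reference
    raise ValueError(f"unknown direction {direction!r}")


def _round2(x: float) -> float:
    # Half-up to match the benchmark tables' presentation, not banker's rounding.
    return float(Decimal(repr(float(x))).quantize(Decimal("0.01"), rounding=ROUND_HALF_UP))


_METRIC_DIRECTIONS = {"MAPE": "reduction", "MAE": "reduction", "R2": "increase"}


def comparison_table(
    reports: dict[str, MetricsReport], subject: str | None = None
) -> pd.DataFrame:
    """Build a metric-by-model comparison table.

    Rows are MAPE/MAE/R2; one column per model.  When ``subject`` names one
    of the models, an extra column per competitor reports the subject's
    relative change against it (reduction for the error metrics, increase
    for R²), rounded to two decimals.
    """
    if not reports:
        raise ValueError("need at least one model")
    table = pd.DataFrame(
        {name: [rep.mape, rep.mae, rep.r2] for name, rep in reports.items()},
        index=["MAPE", "MAE", "R2"],
    )
    if subject is not None:
        if subject not in reports:
            raise ValueError(f"subject model {subject!r} not in reports")
        subj = reports[subject]
        for name, rep in reports.items():
            if name == subject:
                continue
            col = []
            for metric, direction in _METRIC_DIRECTIONS.items():
                ref = getattr(rep, metric.lower())
                new = getattr(subj, metric.lower())
                col.append(_round2(relative_change(ref, new, direction)))
            table[f"{subject} vs {name} (%)"] = col
    return table


def compare_models(
    results: dict[str, EvaluationPair], subject: str | None = None
) -> pd.DataFrame:
    """Evaluate several models against the same actuals and tabulate.

    ``results`` maps model name to its evaluation pair; all pairs must share
    the same actual vector (the fairness contract of a benchmark).
    """
    if not results:
        raise ValueError("need at least one model")
    pairs = list(results.values())
    ref_actual = pairs[0].actual
    for name, p in results.items():
        if p.actual.shape != ref_actual.shape or not np.array_equal(p.actual, ref_actual):
            raise ValueError(f"model {name!r} evaluated against different actuals")
    reports = {name: MetricsReport.from_pair(p) for name, p in results.items()}
    return comparison_table(reports, subject=subject)
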