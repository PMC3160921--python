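"""Population-level metrics: CSMF errors, CSMF accuracy, and regression
diagnostics of estimated against true cause fractions.

The headline metric is CSMF accuracy,

    accuracy = 1 - sum_j |pred_j - true_j| / (2 * (1 - min_j true_j)),

where the denominator is the largest total absolute error any prediction
can make against the given truth (attained by assigning 100% of deaths
to the cause with the smallest true fraction).  Accuracy therefore runs
from 0 (worst possible method) to 1 (no error) regardless of the number
of causes.

Per-cause CSMF estimation behaviour across many test compositions is
summarized by an OLS fit of the estimated fraction on the true fraction:
the intercept measures how much a method assigns to a cause absent from
the data, the slope how the estimate tracks the truth (below 1 for any
non-perfect method), and the residual SD how noisy the estimate is at a
fixed truth.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import statsmodels.api as sm

from .core import CSMFVector, DataError

logger = logging.getLogger("vametrics")


@dataclass(frozen=True)
class CSMFErrorSet:
    cause: str
    absolute_error: float
    relative_error: float  # NaN when the true fraction is 0


@dataclass(frozen=True)
class RegressionSummary:
    """OLS fit of estimated on true fraction for one cause."""

    cause: str
    intercept: float
    slope: float
    rmse: float


def _check_same_causes(true: CSMFVector, pred: CSMFVector) -> None:
    if true.causes != pred.causes:
        raise DataError("true and predicted CSMF vectors use different cause lists")


def absolute_csmf_error(true: CSMFVector, pred: CSMFVector, cause: str) -> float:
    """|pred_j - true_j| for the named cause."""
    _check_same_causes(true, pred)
    return abs(pred[cause] - true[cause])


def relative_csmf_error(true: CSMFVector, pred: CSMFVector, cause: str) -> float:
    """|pred_j - true_j| / true_j; NaN (logged) when true_j = 0."""
    _check_same_causes(true, pred)
    t = true[cause]
    if t == 0:
        logger.warning("relative CSMF error undefined for %r: true fraction is 0", cause)
        return math.nan
    return abs(pred[cause] - t) / t


def total_absolute_error(true: CSMFVector, pred: CSMFVector) -> float:
    """Sum of |pred_j - true_j| over causes."""
    _check_same_causes(true, pred)
    return float(np.abs(pred.fractions - true.fractions).sum())


def max_total_error(true: CSMFVector) -> float:
    """Largest possible total absolute CSMF error against `true`.

    Attained by predicting all deaths from the cause with the smallest
    true fraction: 2 * (1 - min_j true_j).
    """
    if true.causes.N < 2:
        raise DataError("the error bound requires at least two causes")
    return 2.0 * (1.0 - float(true.fractions.min()))


def csmf_accuracy(true: CSMFVector, pred: CSMFVector) -> float:
    """1 - total absolute error / maximum possible total error; in [0, 1]."""
    _check_same_causes(true, pred)
    return 1.0 - total_absolute_error(true, pred) / max_total_error(true)


def csmf_error_sets(true: CSMFVector, pred: CSMFVector) -> list[CSMFErrorSet]:
    return [
        CSMFErrorSet(
            cause=c,
            absolute_error=absolute_csmf_error(true, pred, c),
            relative_error=relative_csmf_error(true, pred, c),
        )
        for c in true.causes
    ]


def ols_line(
    x: np.ndarray, y: np.ndarray, cause: str = "", rmse_denominator: str = "n"
) -> RegressionSummary:
    """Unweighted OLS of y on x with an intercept.

    `rmse_denominator` is "n" (maximum-likelihood residual SD, default)
    or "n-2" (the regression convention).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 3:
        raise DataError("need at least 3 (true, predicted) pairs for regression")
    if np.var(x) == 0:
        raise DataError("true fractions are constant; slope is unidentifiable")
    if rmse_denominator not in ("n", "n-2"):
        raise DataError(f"rmse_denominator must be 'n' or 'n-2', got {rmse_denominator!r}")
    fit = sm.OLS(y, sm.add_constant(x)).fit()
    intercept, slope = fit.params
    denom = x.size if rmse_denominator == "n" else x.size - 2
    rmse = math.sqrt(float(np.sum(fit.resid**2)) / denom)
    return RegressionSummary(cause=cause, intercept=float(intercept),
                             slope=float(slope), rmse=rmse)


def csmf_regression(
    pairs: Sequence[tuple[CSMFVector, CSMFVector]],
    cause: str,
    rmse_denominator: str = "n",
) -> RegressionSummary:
    """OLS of predicted on true fraction for one cause across datasets.

    Each pair is (true, predicted) for one test dataset; the fit needs
    at least three pairs and non-constant true fractions.
    """
    for true, pred in pairs:
        _check_same_causes(true, pred)
    x = np.array([true[cause] for true, _ in pairs])
    y = np.array([pred[cause] for _, pred in pairs])
    return ols_line(x, y, cause=cause, rmse_denominator=rmse_denominator)
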