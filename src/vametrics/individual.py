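"""Metrics for individual-level cause assignment.

The central quantity is the chance-corrected concordance (CCC).  For a
cause j with per-cause sensitivity s_j (diagonal count over row total)
and N causes,

    CCC_j = (s_j - 1/N) / (1 - 1/N)

so 0 marks the accuracy of uniform random assignment and 1 perfect
assignment; values below chance are negative, bounded by -1/(N-1).  The
overall CCC is a weighted mean of the per-cause values; equal weights
are the default because they make results comparable across studies with
different cause compositions.

For methods that rank several candidate causes per death, the top-k
concordance C(k) — the fraction of deaths whose true cause appears among
the k highest-ranked predictions — is chance-corrected the same way
against the partial chance concordance PC(k), giving PCCC(k).

Cohen's kappa is included for comparison: unlike CCC, its expected
agreement is built from the dataset's own marginals, which is exactly
why it drifts with the cause composition of the test set.

Metrics that are mathematically undefined for a given table (a cause
with no true deaths, expected agreement of 1) return NaN and log a
warning, so aggregations can exclude rather than propagate them.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .core import (
    CauseList,
    ConfusionTable,
    DataError,
    UndefinedMetricError,
    ValidationDataset,
    build_confusion,
)

logger = logging.getLogger("vametrics")

#: Conventions for the partial chance concordance PC(k).  "rank" models
#: random assignment as a uniform random ranking without duplicates,
#: PC(k) = k/N; "replacement" models k independent uniform guesses,
#: PC(k) = 1 - ((N-1)/N)**k, and does not reach 1 at k = N.
PC_CONVENTIONS = ("rank", "replacement")

WeightScheme = Union[str, Sequence[float]]


@dataclass(frozen=True)
class CauseMetricSet:
    """Per-cause individual-assignment metrics (NaN where undefined)."""

    cause: str
    sensitivity: float
    specificity: float
    ccc: float


@dataclass(frozen=True)
class OverallMetricSet:
    """Dataset-level individual-assignment metrics."""

    kappa: float
    overall_ccc: float
    weights_used: dict[str, float]
    pccc_by_k: dict[int, float]


def sensitivity(conf: ConfusionTable, cause: str) -> float:
    """Fraction of true deaths from `cause` assigned to it (diagonal/row)."""
    j = conf.causes.index(cause)
    row = conf.row_totals[j]
    if row == 0:
        logger.warning("sensitivity undefined for %r: no true deaths", cause)
        return math.nan
    return float(conf.counts[j, j] / row)


def specificity(conf: ConfusionTable, cause: str) -> float:
    """Fraction of deaths from other causes not assigned to `cause`."""
    j = conf.causes.index(cause)
    off_total = conf.grand_total - conf.row_totals[j]
    if off_total == 0:
        logger.warning("specificity undefined for %r: no off-cause deaths", cause)
        return math.nan
    false_positives = conf.column_totals[j] - conf.counts[j, j]
    return float((off_total - false_positives) / off_total)


def chance_corrected_concordance(conf: ConfusionTable, cause: str) -> float:
    """CCC_j = (sensitivity_j - 1/N) / (1 - 1/N).

    Zero at the accuracy of uniform random assignment (1/N correct),
    one for perfect assignment, negative (down to -1/(N-1)) below chance.
    NaN when the cause has no true deaths in the table.
    """
    sens = sensitivity(conf, cause)
    n = conf.causes.N
    return (sens - 1.0 / n) / (1.0 - 1.0 / n)


def per_cause_metrics(conf: ConfusionTable) -> list[CauseMetricSet]:
    return [
        CauseMetricSet(
            cause=c,
            sensitivity=sensitivity(conf, c),
            specificity=specificity(conf, c),
            ccc=chance_corrected_concordance(conf, c),
        )
        for c in conf.causes
    ]


def _resolve_weights(
    conf: ConfusionTable, weights: WeightScheme, defined: np.ndarray
) -> np.ndarray:
    """Weight vector over causes, renormalized over the defined ones."""
    n = conf.causes.N
    if isinstance(weights, str):
        if weights == "equal":
            w = np.ones(n)
        elif weights in ("test-set", "test_set"):
            w = conf.row_totals / conf.grand_total
        else:
            raise DataError(f"unknown weight scheme {weights!r}")
    else:
        w = np.asarray(list(weights), dtype=float)
        if w.shape != (n,):
            raise DataError(f"need one weight per cause ({n}), got shape {w.shape}")
        if np.any(w < 0):
            raise DataError("weights must be nonnegative")
        if abs(w.sum() - 1.0) > 1e-9:
            raise DataError(f"weights sum to {w.sum()!r}, not 1")
    w = np.where(defined, w, 0.0)
    total = w.sum()
    if total == 0:
        raise UndefinedMetricError("no cause has both a defined CCC and weight > 0")
    return w / total


def overall_ccc(
    conf: ConfusionTable,
    weights: WeightScheme = "equal",
    exclude_undefined: bool = True,
) -> float:
    """Weighted mean of per-cause chance-corrected concordances.

    `weights` is "equal" (recommended default), "test-set" (the test
    dataset's own true-cause fractions), or an explicit vector summing
    to 1.  Causes with undefined CCC (no true deaths) are excluded and
    the remaining weights renormalized when ``exclude_undefined`` is
    set; otherwise their presence raises :class:`UndefinedMetricError`.
    """
    cccs = np.array(
        [chance_corrected_concordance(conf, c) for c in conf.causes]
    )
    defined = ~np.isnan(cccs)
    if not exclude_undefined and not defined.all():
        missing = [c for c, d in zip(conf.causes, defined) if not d]
        raise UndefinedMetricError(f"CCC undefined for causes {missing!r}")
    n_excluded = int((~defined).sum())
    if n_excluded:
        logger.warning("overall CCC excludes %d undefined cause(s)", n_excluded)
    w = _resolve_weights(conf, weights, defined)
    return float(np.nansum(w * cccs))


def ccc_weights(conf: ConfusionTable, weights: WeightScheme = "equal") -> dict[str, float]:
    """The per-cause weights actually used by :func:`overall_ccc`."""
    cccs = np.array([chance_corrected_concordance(conf, c) for c in conf.causes])
    w = _resolve_weights(conf, weights, ~np.isnan(cccs))
    return {c: float(x) for c, x in zip(conf.causes, w)}


def cohen_kappa(conf: ConfusionTable) -> float:
    """Cohen's kappa: (P_obs - P_exp) / (1 - P_exp).

    P_obs is the overall agreement fraction (trace over total); P_exp is
    the agreement expected from the row and column marginals,
    sum_i (row_i/total) * (col_i/total).  NaN when P_exp = 1 (all mass
    in a single cell).
    """
    total = conf.grand_total
    p_obs = float(np.trace(conf.counts)) / total
    p_exp = float(np.sum(conf.row_totals * conf.column_totals)) / total**2
    if 1.0 - p_exp < 1e-12:
        logger.warning("kappa undefined: expected agreement is 1")
        return math.nan
    return (p_obs - p_exp) / (1.0 - p_exp)


def top_k_concordance(dataset: ValidationDataset, k: int) -> float:
    """Fraction of deaths whose true cause is among the top k predictions.

    Single-cause predictions are treated as ranked lists of length one.
    Non-decreasing in k for every dataset.
    """
    n = dataset.causes.N
    if not 1 <= k <= n:
        raise DataError(f"k must be in [1, {n}], got {k}")
    hits = 0
    for rec in dataset.records:
        if isinstance(rec.prediction, str):
            top = (rec.prediction,)
        else:
            top = tuple(c for c, _ in rec.prediction[:k])
        if rec.true_cause in top:
            hits += 1
    return hits / len(dataset.records)


def partial_chance_concordance(k: int, N: int, convention: str = "rank") -> float:
    """PC(k): probability the true cause lands in a random top-k list.

    Under the default "rank" convention a random method produces a
    uniform random ranking of the N causes, so PC(k) = k/N — which gives
    PC(1) = 1/N and PC(N) = 1.  The "replacement" convention (k
    independent uniform guesses, duplicates allowed) gives
    1 - ((N-1)/N)**k and is offered for sensitivity analysis only.
    """
    if N < 2:
        raise DataError("N must be at least 2")
    if not 1 <= k <= N:
        raise DataError(f"k must be in [1, {N}], got {k}")
    if convention == "rank":
        return k / N
    if convention == "replacement":
        return 1.0 - ((N - 1) / N) ** k
    raise DataError(f"unknown PC(k) convention {convention!r}; use one of {PC_CONVENTIONS}")


def pccc(dataset: ValidationDataset, k: int, convention: str = "rank") -> float:
    """Partial chance-corrected concordance for the top k causes.

    PCCC(k) = (C(k) - PC(k)) / (1 - PC(k)) with C(k) the top-k
    concordance.  Undefined at k = N, where PC(k) = 1.
    """
    n = dataset.causes.N
    if not 1 <= k <= n:
        raise DataError(f"k must be in [1, {n}], got {k}")
    if k == n:
        raise UndefinedMetricError(
            "PCCC(k) is not defined at k = N: chance concordance is 1"
        )
    c = top_k_concordance(dataset, k)
    pc = partial_chance_concordance(k, n, convention)
    return (c - pc) / (1.0 - pc)


def overall_metrics(
    dataset: ValidationDataset,
    ks: Sequence[int] = (),
    weights: WeightScheme = "equal",
    convention: str = "rank",
) -> OverallMetricSet:
    """Convenience bundle: kappa, overall CCC, and PCCC for each k."""
    conf = build_confusion(dataset)
    return OverallMetricSet(
        kappa=cohen_kappa(conf),
        overall_ccc=overall_ccc(conf, weights=weights),
        weights_used=ccc_weights(conf, weights),
        pccc_by_k={k: pccc(dataset, k, convention) for k in ks},
    )
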