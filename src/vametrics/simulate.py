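"""Simulation of hypothetical VA methods from misclassification matrices.

A cause-assignment method, for validation purposes, is fully described
by its misclassification matrix: the row-stochastic N x N matrix of
probabilities p_ij = P(predicted cause j | true cause i).  Holding this
matrix fixed while the cause composition of the test set varies isolates
how much of each metric is driven by composition alone.

Two built-in three-cause methods are provided.  Method 2 dominates
method 1 — it differs only in a higher probability of assigning true
cause-A deaths to cause A — yet on many individual test sets method 1
shows the smaller CSMF error, which is the instability the resampling
protocol is designed to expose.

:func:`run_validation_experiment` runs the full study: for each of
`n_draws` Dirichlet compositions, one set of true causes is drawn and
shared by all methods (paired design), predictions are simulated from
each matrix, and all individual and CSMF metrics are computed per draw.
In analytic mode, expected (fractional) confusion counts replace
sampling, making composition-invariant metrics exactly constant.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from . import csmf as csmf_metrics
from . import individual
from .core import (
    CauseList,
    ConfusionTable,
    CSMFVector,
    DataError,
    DeathRecord,
    ValidationDataset,
)
from .csmf import ols_line
from .resampling import ResamplingConfig, draw_composition

_ABC = ("A", "B", "C")

_METHOD_MATRICES = {
    "method1": np.array(
        [
            [0.70, 0.03, 0.27],
            [0.04, 0.60, 0.36],
            [0.065, 0.585, 0.35],
        ]
    ),
    "method2": np.array(
        [
            [0.80, 0.02, 0.18],
            [0.04, 0.60, 0.36],
            [0.065, 0.585, 0.35],
        ]
    ),
}


@dataclass(frozen=True)
class MisclassificationMatrix:
    """Row-stochastic matrix of assignment probabilities.

    probs[i, j] = P(predicted cause j | true cause i); every row sums
    to 1 within 1e-9.
    """

    causes: CauseList
    probs: np.ndarray

    def __post_init__(self) -> None:
        probs = np.asarray(self.probs, dtype=float)
        n = self.causes.N
        if probs.shape != (n, n):
            raise DataError(f"matrix must be {n}x{n}, got {probs.shape}")
        if np.any(probs < 0) or np.any(probs > 1):
            raise DataError("matrix entries must lie in [0, 1]")
        row_sums = probs.sum(axis=1)
        bad = np.where(np.abs(row_sums - 1.0) > 1e-9)[0]
        if bad.size:
            raise DataError(
                f"rows must sum to 1; row(s) {[self.causes.labels[i] for i in bad]} "
                f"sum to {row_sums[bad]}"
            )
        probs.setflags(write=False)
        object.__setattr__(self, "probs", probs)

    @classmethod
    def identity(cls, causes: CauseList) -> "MisclassificationMatrix":
        """The perfect method: every death assigned its true cause."""
        return cls(causes, np.eye(causes.N))

    def row(self, cause: str) -> np.ndarray:
        return self.probs[self.causes.index(cause)]


def builtin_method(name: str) -> MisclassificationMatrix:
    """Built-in three-cause hypothetical methods "method1" and "method2"."""
    if name not in _METHOD_MATRICES:
        raise DataError(
            f"unknown built-in method {name!r}; available: {sorted(_METHOD_MATRICES)}"
        )
    return MisclassificationMatrix(CauseList(_ABC), _METHOD_MATRICES[name])


def simulate_predictions(
    matrix: MisclassificationMatrix,
    true_causes: Sequence[str],
    rng: np.random.Generator,
) -> ValidationDataset:
    """Simulate single-cause predictions for the given true causes.

    Each record's prediction is drawn independently from the matrix row
    of its true cause.
    """
    if not len(true_causes):
        raise DataError("need at least one true cause")
    causes = matrix.causes
    labels = causes.labels
    records = []
    for i, true in enumerate(true_causes):
        row = matrix.row(true)
        pred = labels[rng.choice(causes.N, p=row)]
        records.append(DeathRecord(id=str(i), true_cause=true, prediction=pred))
    return ValidationDataset(causes, tuple(records))


def expected_confusion(
    matrix: MisclassificationMatrix, composition: CSMFVector
) -> ConfusionTable:
    """Expected (fractional) confusion table: diag(composition) @ probs.

    Grand total is 1; row totals equal the composition exactly.
    """
    if matrix.causes != composition.causes:
        raise DataError("matrix and composition use different cause lists")
    return ConfusionTable(matrix.causes, composition.fractions[:, None] * matrix.probs)


def sample_confusion(
    matrix: MisclassificationMatrix,
    true_counts: np.ndarray,
    rng: np.random.Generator,
) -> ConfusionTable:
    """Sampled confusion table given true-cause counts.

    Row i is multinomial(true_counts[i], probs[i]) — identical in
    distribution to simulating each death's prediction independently.
    """
    counts = np.zeros((matrix.causes.N, matrix.causes.N))
    for i, m in enumerate(np.asarray(true_counts, dtype=int)):
        if m > 0:
            counts[i] = rng.multinomial(m, matrix.probs[i])
    return ConfusionTable(matrix.causes, counts)


def sample_confusions_coupled(
    matrices: Mapping[str, MisclassificationMatrix],
    true_counts: np.ndarray,
    rng: np.random.Generator,
) -> dict[str, ConfusionTable]:
    """Sampled confusion tables for several methods on the same deaths.

    One uniform variate is drawn per death and inverted through each
    method's row CDF (common random numbers), so each method's marginal
    distribution is exactly multinomial while methods agree wherever
    their row probabilities overlap.  This is the paired analogue of
    applying every method to the same test dataset: a method that
    differs only by a better diagonal entry reclassifies some of the
    same deaths rather than redrawing them.
    """
    names = list(matrices)
    causes = matrices[names[0]].causes
    n = causes.N
    cdfs = {name: np.cumsum(m.probs, axis=1) for name, m in matrices.items()}
    counts = {name: np.zeros((n, n)) for name in names}
    for i, m in enumerate(np.asarray(true_counts, dtype=int)):
        if m == 0:
            continue
        u = rng.random(m)
        for name in names:
            assigned = np.searchsorted(cdfs[name][i], u, side="left")
            counts[name][i] = np.bincount(np.minimum(assigned, n - 1), minlength=n)
    return {name: ConfusionTable(causes, counts[name]) for name in names}


@dataclass
class ExperimentResult:
    """Long-format results of a multi-method validation experiment.

    per_cause: one row per (draw, method, cause) with true/predicted
    fractions, errors, sensitivity, specificity, and CCC.
    overall: one row per (draw, method) with kappa, overall CCC (equal
    weights), total absolute CSMF error, and CSMF accuracy.
    """

    causes: CauseList
    methods: tuple[str, ...]
    per_cause: pd.DataFrame
    overall: pd.DataFrame
    config: ResamplingConfig

    def summary(self) -> pd.DataFrame:
        """Mean/median/max/min of every metric by method (and cause)."""
        stats = ["mean", "median", "max", "min"]
        cause_cols = ["sensitivity", "specificity", "ccc",
                      "absolute_csmf_error", "relative_csmf_error"]
        by_cause = (
            self.per_cause.groupby(["method", "cause"])[cause_cols]
            .agg(stats)
            .reset_index()
        )
        by_cause.columns = ["_".join(c).rstrip("_") for c in by_cause.columns]
        overall_cols = ["kappa", "overall_ccc", "total_absolute_csmf_error",
                        "csmf_accuracy"]
        overall = self.overall.groupby("method")[overall_cols].agg(stats).reset_index()
        overall.columns = ["_".join(c).rstrip("_") for c in overall.columns]
        overall.insert(1, "cause", "ALL")
        return pd.concat([by_cause, overall], ignore_index=True)

    def regressions(self, rmse_denominator: str = "n") -> pd.DataFrame:
        """Per-method, per-cause OLS of predicted on true CSMF."""
        rows = []
        for (method, cause), grp in self.per_cause.groupby(["method", "cause"]):
            fit = ols_line(
                grp["true_csmf"].to_numpy(),
                grp["predicted_csmf"].to_numpy(),
                cause=cause,
                rmse_denominator=rmse_denominator,
            )
            rows.append(
                {"method": method, "cause": cause, "intercept": fit.intercept,
                 "slope": fit.slope, "rmse": fit.rmse}
            )
        return pd.DataFrame(rows)


def _metrics_for_confusion(conf: ConfusionTable) -> tuple[dict, list[dict]]:
    """Overall and per-cause metric dicts for one (draw, method)."""
    causes = conf.causes
    true = CSMFVector(causes, conf.row_totals / conf.grand_total)
    pred = CSMFVector(causes, conf.column_totals / conf.grand_total)
    per_cause = []
    for c in causes:
        per_cause.append(
            {
                "cause": c,
                "true_csmf": true[c],
                "predicted_csmf": pred[c],
                "absolute_csmf_error": csmf_metrics.absolute_csmf_error(true, pred, c),
                "relative_csmf_error": csmf_metrics.relative_csmf_error(true, pred, c),
                "sensitivity": individual.sensitivity(conf, c),
                "specificity": individual.specificity(conf, c),
                "ccc": individual.chance_corrected_concordance(conf, c),
            }
        )
    overall = {
        "kappa": individual.cohen_kappa(conf),
        "overall_ccc": individual.overall_ccc(conf, weights="equal"),
        "total_absolute_csmf_error": csmf_metrics.total_absolute_error(true, pred),
        "csmf_accuracy": csmf_metrics.csmf_accuracy(true, pred),
    }
    return overall, per_cause


def run_validation_experiment(
    matrices: Mapping[str, MisclassificationMatrix],
    config: Optional[ResamplingConfig] = None,
) -> ExperimentResult:
    """The full composition-variation study for one or more methods.

    Per draw: one composition from Dirichlet(alpha); in finite-sample
    mode one multinomial set of true-cause counts shared by every method
    (paired design), with predictions coupled across methods by common
    random numbers (see :func:`sample_confusions_coupled`); in analytic
    mode the expected confusion table diag(p) @ M.  All metrics are
    computed per draw and returned in long format.
    """
    if not matrices:
        raise DataError("need at least one misclassification matrix")
    config = config or ResamplingConfig()
    method_names = tuple(matrices)
    causes = matrices[method_names[0]].causes
    for name, m in matrices.items():
        if m.causes != causes:
            raise DataError(f"matrix {name!r} uses a different cause list")
    alpha = config.alphas(causes.N)

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_draws)

    per_cause_rows: list[dict] = []
    overall_rows: list[dict] = []
    for draw, child in enumerate(children):
        rng = np.random.default_rng(child)
        comp = draw_composition(causes, alpha, rng)
        if config.analytic:
            confs = {name: expected_confusion(matrices[name], comp) for name in method_names}
        else:
            true_counts = rng.multinomial(config.deaths_per_dataset, comp.fractions)
            confs = sample_confusions_coupled(matrices, true_counts, rng)
        for name in method_names:
            overall, per_cause = _metrics_for_confusion(confs[name])
            overall_rows.append({"draw": draw, "method": name, **overall})
            for row in per_cause:
                per_cause_rows.append({"draw": draw, "method": name, **row})

    return ExperimentResult(
        causes=causes,
        methods=method_names,
        per_cause=pd.DataFrame(per_cause_rows),
        overall=pd.DataFrame(overall_rows),
        config=config,
    )


def compare_methods(
    result: ExperimentResult,
    method_a: str,
    method_b: str,
    metric: str = "absolute_csmf_error",
) -> pd.DataFrame:
    """Per-cause paired win counts between two methods.

    For each cause, counts the draws where each method has the strictly
    smaller value of `metric` (absolute CSMF error by default); ties are
    reported separately.  Requires both methods evaluated on the same
    paired draws.
    """
    for name in (method_a, method_b):
        if name not in result.methods:
            raise DataError(f"method {name!r} not present in the experiment result")
    wide = result.per_cause.pivot_table(
        index=["draw", "cause"], columns="method", values=metric
    )
    if wide[[method_a, method_b]].isna().any().any():
        raise DataError("methods are not paired on identical draws")
    rows = []
    for cause in result.causes:
        sub = wide.xs(cause, level="cause")
        a, b = sub[method_a], sub[method_b]
        rows.append(
            {
                "cause": cause,
                f"{method_a}_wins": int((a < b).sum()),
                f"{method_b}_wins": int((b < a).sum()),
                "ties": int((a == b).sum()),
            }
        )
    return pd.DataFrame(rows)
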