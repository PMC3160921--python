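"""Dirichlet resampling of test-set cause compositions.

Most validation metrics depend on the cause composition of the test
dataset, so a single test set can rank two methods in the wrong order.
The protocol implemented here evaluates a metric across many test sets
whose compositions are drawn from an uninformative Dirichlet
distribution (all concentration parameters 1, i.e. uniform over the
simplex) and reports the median across draws.  For each drawn
composition, a new dataset is built by sampling the source records with
replacement within each true cause, with cause counts drawn
multinomially from the composition — so the method's conditional
misclassification behaviour is preserved while the composition varies.

Draws continue for a fixed number of iterations (default 500); the
running median is monitored at a check interval and the first draw at
which it stabilizes (relative change below a tolerance, default the
0.5% rule) is reported.  Early stopping at stabilization is opt-in.

Randomness: the root seed spawns one independent substream per draw, so
per-draw results do not depend on execution order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .core import (
    CauseLabelError,
    CauseList,
    CSMFVector,
    DataError,
    UndefinedMetricError,
    ValidationDataset,
)

#: Sentinel for expected-count evaluation instead of finite samples.
ANALYTIC = "analytic"


@dataclass
class ResamplingConfig:
    """Protocol parameters for composition resampling.

    deaths_per_dataset is a positive integer, or the string "analytic"
    to evaluate on expected compositions without sampling deaths.
    median_tolerance is the relative change in the running median below
    which it counts as stabilized (default 0.5%).
    """

    n_draws: int = 500
    deaths_per_dataset: Union[int, str] = 1000
    dirichlet_alpha: Union[float, Sequence[float]] = 1.0
    seed: int = 0
    median_tolerance: float = 0.005
    check_interval: int = 10
    stop_when_stable: bool = False

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise DataError("n_draws must be positive")
        if self.deaths_per_dataset != ANALYTIC and (
            not isinstance(self.deaths_per_dataset, int) or self.deaths_per_dataset < 1
        ):
            raise DataError("deaths_per_dataset must be a positive integer or 'analytic'")
        if self.median_tolerance < 0:
            raise DataError("median_tolerance must be nonnegative")
        if self.check_interval < 1:
            raise DataError("check_interval must be positive")

    @property
    def analytic(self) -> bool:
        return self.deaths_per_dataset == ANALYTIC

    def alphas(self, n_causes: int) -> np.ndarray:
        if np.isscalar(self.dirichlet_alpha):
            alpha = np.full(n_causes, float(self.dirichlet_alpha))
        else:
            alpha = np.asarray(list(self.dirichlet_alpha), dtype=float)
            if alpha.shape != (n_causes,):
                raise DataError(
                    f"need one alpha per cause ({n_causes}), got shape {alpha.shape}"
                )
        if np.any(alpha <= 0):
            raise DataError("Dirichlet concentration parameters must be positive")
        return alpha


@dataclass
class DrawTrace:
    """Per-draw record of composition and metric value, plus the
    running-median curve sampled at each check interval."""

    draws: pd.DataFrame      # columns: draw, csmf_<cause>..., value
    running: pd.DataFrame    # columns: n_draws, median

    def to_csv(self, draws_path, running_path) -> None:
        self.draws.to_csv(draws_path, index=False)
        self.running.to_csv(running_path, index=False)


@dataclass(frozen=True)
class MedianSummary:
    median: float
    n_draws: int
    n_undefined: int
    stabilized_at: Optional[int]  # draw count at first stabilization, or None


def draw_composition(
    causes: CauseList,
    alpha: Union[float, Sequence[float]],
    rng: np.random.Generator,
) -> CSMFVector:
    """One cause composition drawn from Dirichlet(alpha).

    alpha = 1 for every cause gives the uninformative (uniform-on-the-
    simplex) distribution whose mean is equal cause fractions.
    """
    if np.isscalar(alpha):
        alpha_vec = np.full(causes.N, float(alpha))
    else:
        alpha_vec = np.asarray(list(alpha), dtype=float)
    if alpha_vec.shape != (causes.N,) or np.any(alpha_vec <= 0):
        raise DataError("alpha must be positive, one value per cause")
    frac = rng.dirichlet(alpha_vec)
    return CSMFVector(causes, frac)


def resample_dataset(
    source: ValidationDataset,
    target: CSMFVector,
    n: int,
    rng: np.random.Generator,
) -> ValidationDataset:
    """Resample `source` with replacement to a new cause composition.

    Cause counts are multinomial with probabilities `target`; within a
    cause, records are drawn uniformly with replacement from that
    cause's source records, so the conditional prediction structure is
    preserved in expectation.
    """
    if source.causes != target.causes:
        raise DataError("source dataset and target composition use different cause lists")
    if n < 1:
        raise DataError("n must be positive")
    by_cause: dict[str, list] = {c: [] for c in source.causes}
    for rec in source.records:
        by_cause[rec.true_cause].append(rec)
    counts = rng.multinomial(n, target.fractions)
    records = []
    for cause, count in zip(source.causes, counts):
        if count == 0:
            continue
        pool = by_cause[cause]
        if not pool:
            raise CauseLabelError(
                f"cannot resample: no source deaths for cause {cause!r} "
                f"(target fraction {target[cause]:.4f})"
            )
        for idx in rng.integers(0, len(pool), size=count):
            records.append(pool[idx])
    return ValidationDataset(source.causes, tuple(records))


def is_stabilized(
    running_medians: Sequence[float], tolerance: float = 0.005
) -> tuple[bool, Optional[int]]:
    """Has the running median stopped moving?

    Returns (stabilized, index) where index is the position in
    `running_medians` (0-based) of the first value whose relative change
    from the previous check is at most `tolerance`.  Needs at least two
    checks; zero previous medians are compared on the absolute scale.
    """
    meds = list(running_medians)
    for i in range(1, len(meds)):
        prev, cur = meds[i - 1], meds[i]
        if math.isnan(prev) or math.isnan(cur):
            continue
        change = abs(cur - prev) / abs(prev) if prev != 0 else abs(cur - prev)
        if change <= tolerance:
            return True, i
    return False, None


def median_over_draws(
    evaluator: Callable[[object], float],
    source: Optional[ValidationDataset],
    config: ResamplingConfig,
    causes: Optional[CauseList] = None,
) -> tuple[MedianSummary, DrawTrace]:
    """Median of a metric across Dirichlet-resampled test datasets.

    In finite-sample mode, `evaluator` is called with each resampled
    :class:`ValidationDataset`; in analytic mode it is called with the
    drawn :class:`CSMFVector` composition itself (and `causes` must be
    given when `source` is None).  Undefined values (NaN) are excluded
    from the median with their count reported.
    """
    if source is not None:
        causes = source.causes
    if causes is None:
        raise DataError("either a source dataset or an explicit cause list is required")
    if not config.analytic and source is None:
        raise DataError("finite-sample resampling requires a source dataset")
    alpha = config.alphas(causes.N)

    root = np.random.SeedSequence(config.seed)
    children = root.spawn(config.n_draws)

    rows = []
    values: list[float] = []
    running_meds: list[float] = []
    running_counts: list[int] = []
    for i, child in enumerate(children):
        rng = np.random.default_rng(child)
        comp = draw_composition(causes, alpha, rng)
        if config.analytic:
            value = float(evaluator(comp))
        else:
            dataset = resample_dataset(source, comp, config.deaths_per_dataset, rng)
            value = float(evaluator(dataset))
        values.append(value)
        rows.append(
            {"draw": i, **{f"csmf_{c}": f for c, f in comp.to_dict().items()},
             "value": value}
        )
        if (i + 1) % config.check_interval == 0:
            arr = np.asarray(values)
            med = float(np.nanmedian(arr)) if not np.all(np.isnan(arr)) else math.nan
            running_meds.append(med)
            running_counts.append(i + 1)
            if config.stop_when_stable:
                stable, _ = is_stabilized(running_meds, config.median_tolerance)
                if stable:
                    break

    arr = np.asarray(values)
    n_undefined = int(np.isnan(arr).sum())
    if n_undefined == len(values):
        raise UndefinedMetricError("the metric was undefined on every draw")
    stable, idx = is_stabilized(running_meds, config.median_tolerance)
    summary = MedianSummary(
        median=float(np.nanmedian(arr)),
        n_draws=len(values),
        n_undefined=n_undefined,
        stabilized_at=running_counts[idx] if stable else None,
    )
    trace = DrawTrace(
        draws=pd.DataFrame(rows),
        running=pd.DataFrame({"n_draws": running_counts, "median": running_meds}),
    )
    return summary, trace
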