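"""Core data model for cause-of-death validation data.

A validation study compares, death by death, the cause assigned by a
verbal-autopsy (VA) method against the true (gold standard) cause.  The
types here carry that comparison: an ordered :class:`CauseList` shared by
every matrix and vector, individual :class:`DeathRecord` entries whose
prediction is either a single cause or a ranked probability list, the
:class:`ValidationDataset` collection, the N x N :class:`ConfusionTable`
of (true, predicted) counts, and :class:`CSMFVector`, a point on the
cause-fraction simplex (cause-specific mortality fractions summing to 1).

All downstream metrics consume these types.  Confusion counts are stored
as floats so that tables of *expected* (fractional) counts — used by the
analytic evaluation mode — share the same type as tallied integer counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Iterator, Sequence, Union

import numpy as np

logger = logging.getLogger("vametrics")

#: Tolerance for probability/fraction sums (malformed inputs are rejected,
#: never silently renormalized).
PROB_TOL = 1e-9


class DataError(ValueError):
    """Malformed input data: bad probabilities, empty datasets, shape errors."""


class CauseLabelError(DataError):
    """A record, matrix, or vector refers to a cause not in the cause list."""


class UndefinedMetricError(ValueError):
    """A requested metric is mathematically undefined for the given input."""


@dataclass(frozen=True)
class CauseList:
    """Ordered, immutable collection of distinct cause labels.

    The ordering fixed at construction is shared by every confusion
    table, misclassification matrix, and CSMF vector built over it.
    Labels are stripped of surrounding whitespace and matched
    case-sensitively; at least two causes are required, since every
    chance-correction below divides by ``1 - 1/N``.
    """

    labels: tuple[str, ...]

    def __post_init__(self) -> None:
        cleaned = tuple(str(label).strip() for label in self.labels)
        if any(not label for label in cleaned):
            raise DataError("cause labels must be non-empty strings")
        if len(set(cleaned)) != len(cleaned):
            raise DataError(f"cause labels must be unique, got {cleaned!r}")
        if len(cleaned) < 2:
            raise DataError("at least two causes are required")
        object.__setattr__(self, "labels", cleaned)
        object.__setattr__(self, "_index", {l: i for i, l in enumerate(cleaned)})

    @property
    def N(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self._index[label]  # type: ignore[attr-defined]
        except KeyError:
            raise CauseLabelError(
                f"unknown cause {label!r}; known causes: {list(self.labels)}"
            ) from None

    def __len__(self) -> int:
        return len(self.labels)

    def __iter__(self) -> Iterator[str]:
        return iter(self.labels)

    def __contains__(self, label: object) -> bool:
        return label in self._index  # type: ignore[attr-defined]


#: A prediction is either a single cause label or a ranked sequence of
#: (cause, probability) pairs, probabilities summing to 1.
Prediction = Union[str, tuple]


def _normalize_prediction(
    prediction: Prediction, causes: CauseList, record_id: str
) -> Prediction:
    """Validate a prediction and return its canonical form.

    Ranked lists are sorted by descending probability, ties broken by
    cause order in the cause list (deterministic).  Probabilities must be
    nonnegative and sum to 1 within ``PROB_TOL``; violations raise
    :class:`DataError` rather than being renormalized.
    """
    if isinstance(prediction, str):
        cause = prediction.strip()
        if cause not in causes:
            raise CauseLabelError(
                f"record {record_id!r}: unknown predicted cause {cause!r}"
            )
        return cause

    pairs = [(str(c).strip(), float(p)) for c, p in prediction]
    names = [c for c, _ in pairs]
    for cause, prob in pairs:
        if cause not in causes:
            raise CauseLabelError(
                f"record {record_id!r}: unknown predicted cause {cause!r}"
            )
        if prob < 0:
            raise DataError(
                f"record {record_id!r}: negative probability {prob} for {cause!r}"
            )
    if len(set(names)) != len(names):
        raise DataError(f"record {record_id!r}: duplicate cause in ranked prediction")
    total = sum(p for _, p in pairs)
    if abs(total - 1.0) > PROB_TOL:
        raise DataError(
            f"record {record_id!r}: ranked probabilities sum to {total!r}, not 1"
        )
    pairs.sort(key=lambda cp: (-cp[1], causes.index(cp[0])))
    return tuple(pairs)


@dataclass(frozen=True)
class DeathRecord:
    """One death: identifier, true cause, and the method's prediction."""

    id: str
    true_cause: str
    prediction: Prediction

    @property
    def is_ranked(self) -> bool:
        return not isinstance(self.prediction, str)

    @property
    def top_cause(self) -> str:
        """Single predicted cause, or the highest-probability ranked cause."""
        if isinstance(self.prediction, str):
            return self.prediction
        return self.prediction[0][0]

    def probabilities(self, causes: CauseList) -> np.ndarray:
        """Prediction as a probability vector over the cause list."""
        vec = np.zeros(causes.N)
        if isinstance(self.prediction, str):
            vec[causes.index(self.prediction)] = 1.0
        else:
            for cause, prob in self.prediction:
                vec[causes.index(cause)] = prob
        return vec


@dataclass(frozen=True)
class ValidationDataset:
    """A cause list plus at least one death record, all validated.

    Construction canonicalizes every record (whitespace-trimmed labels,
    ranked lists sorted by descending probability) and rejects records
    referencing causes outside the cause list, naming the offending
    record id in the error.
    """

    causes: CauseList
    records: tuple[DeathRecord, ...]

    def __post_init__(self) -> None:
        records = tuple(self.records)
        if not records:
            raise DataError("a validation dataset needs at least one record")
        normalized = []
        for rec in records:
            true = rec.true_cause.strip()
            if true not in self.causes:
                raise CauseLabelError(
                    f"record {rec.id!r}: unknown true cause {rec.true_cause!r}"
                )
            pred = _normalize_prediction(rec.prediction, self.causes, rec.id)
            normalized.append(DeathRecord(rec.id, true, pred))
        object.__setattr__(self, "records", tuple(normalized))

    def __len__(self) -> int:
        return len(self.records)

    @property
    def has_ranked(self) -> bool:
        return any(rec.is_ranked for rec in self.records)


@dataclass(frozen=True)
class ConfusionTable:
    """N x N counts of (true cause, predicted cause) pairs.

    Rows index the true cause, columns the predicted cause, so
    ``counts[i, j] / row_totals[i]`` estimates the misclassification
    probability P(predicted = j | true = i).  Counts are nonnegative and
    may be fractional (expected counts in analytic mode).
    """

    causes: CauseList
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        n = self.causes.N
        if counts.shape != (n, n):
            raise DataError(f"confusion counts must be {n}x{n}, got {counts.shape}")
        if np.any(counts < 0) or not np.all(np.isfinite(counts)):
            raise DataError("confusion counts must be finite and nonnegative")
        if counts.sum() <= 0:
            raise DataError("confusion table must contain at least one death")
        counts.setflags(write=False)
        object.__setattr__(self, "counts", counts)

    @property
    def row_totals(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    @property
    def column_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    @property
    def grand_total(self) -> float:
        return float(self.counts.sum())

    def row_probabilities(self) -> np.ndarray:
        """Row-normalized counts: the estimated misclassification matrix.

        Rows with zero total are returned as NaN.
        """
        totals = self.row_totals
        with np.errstate(invalid="ignore", divide="ignore"):
            probs = self.counts / totals[:, None]
        probs[totals == 0] = np.nan
        return probs


@dataclass(frozen=True)
class CSMFVector:
    """Cause-specific mortality fractions: a point on the N-simplex."""

    causes: CauseList
    fractions: np.ndarray

    def __post_init__(self) -> None:
        frac = np.asarray(self.fractions, dtype=float)
        if frac.shape != (self.causes.N,):
            raise DataError(
                f"expected {self.causes.N} fractions, got shape {frac.shape}"
            )
        if np.any(frac < -PROB_TOL) or np.any(frac > 1 + PROB_TOL):
            raise DataError("CSMF fractions must lie in [0, 1]")
        if abs(frac.sum() - 1.0) > PROB_TOL:
            raise DataError(f"CSMF fractions sum to {frac.sum()!r}, not 1")
        frac = np.clip(frac, 0.0, 1.0)
        frac.setflags(write=False)
        object.__setattr__(self, "fractions", frac)

    def __getitem__(self, cause: str) -> float:
        return float(self.fractions[self.causes.index(cause)])

    def to_dict(self) -> dict[str, float]:
        return {c: float(f) for c, f in zip(self.causes, self.fractions)}


def build_confusion(dataset: ValidationDataset) -> ConfusionTable:
    """Tally the N x N classification table of true versus assigned cause.

    Ranked predictions contribute their top-ranked cause.
    """
    n = dataset.causes.N
    counts = np.zeros((n, n))
    for rec in dataset.records:
        i = dataset.causes.index(rec.true_cause)
        j = dataset.causes.index(rec.top_cause)
        counts[i, j] += 1
    return ConfusionTable(dataset.causes, counts)


def csmf_of_true(dataset: ValidationDataset) -> CSMFVector:
    """Cause fractions of the true causes in the dataset."""
    counts = np.zeros(dataset.causes.N)
    for rec in dataset.records:
        counts[dataset.causes.index(rec.true_cause)] += 1
    return CSMFVector(dataset.causes, counts / counts.sum())


def csmf_of_predicted(dataset: ValidationDataset) -> CSMFVector:
    """Cause fractions implied by the predictions.

    For single-cause predictions this is the column marginal of the
    confusion table divided by the total; for ranked predictions, the
    mean of the per-death probability vectors.
    """
    total = np.zeros(dataset.causes.N)
    for rec in dataset.records:
        total += rec.probabilities(dataset.causes)
    return CSMFVector(dataset.causes, total / len(dataset.records))
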