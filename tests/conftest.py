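import numpy as np
import pytest

from vametrics import (
    CauseList,
    DeathRecord,
    ValidationDataset,
    builtin_method,
)


@pytest.fixture
def causes_abc():
    return CauseList(("A", "B", "C"))


@pytest.fixture
def method1():
    return builtin_method("method1")


@pytest.fixture
def method2():
    return builtin_method("method2")


@pytest.fixture
def rng():
    return np.random.default_rng(20110804)


def make_dataset(causes, pairs):
    """Dataset from (true, predicted) label pairs."""
    records = tuple(
        DeathRecord(id=str(i), true_cause=t, prediction=p)
        for i, (t, p) in enumerate(pairs)
    )
    return ValidationDataset(causes, records)


def random_dataset(rng, n_causes=None, n_records=None):
    """Small random single-cause dataset for oracle comparisons."""
    if n_causes is None:
        n_causes = int(rng.integers(2, 6))
    if n_records is None:
        n_records = int(rng.integers(1, 51))
    labels = tuple(chr(ord("A") + i) for i in range(n_causes))
    causes = CauseList(labels)
    pairs = [
        (labels[rng.integers(n_causes)], labels[rng.integers(n_causes)])
        for _ in range(n_records)
    ]
    return make_dataset(causes, pairs)
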